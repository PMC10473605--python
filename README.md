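# swmkit

Analysis pipeline for **individual differences in spatial working-memory
(sWM) strategy**: how strongly a person relies on precise *fine-grained*
location memory versus coarse *categorical* coding, and how those
tendencies relate to brain-network activity pooled across several fMRI
studies.

## The problem and the model

In a delayed-response task, a participant memorizes the angle of a target
(constant amplitude from fixation, never on the cardinal axes) and, after a
delay, reproduces it with a joystick. Responses are systematically pulled
toward the nearest quadrant diagonal (45°/135°/225°/315°) — the signature of
categorical coding with the quadrant diagonal as prototype — on top of
trial-to-trial Gaussian imprecision.

`swmkit` decomposes each trial's angular error *θ* into:

- **angular bias** *θb′*: the participant's systematic mean error toward the
  nearest diagonal at each distinct distance |d| from it, summarized per
  participant as the RMS of the per-|d| bias estimates;
- **pure angular error** *θ′*: the residual after subtracting that bias
  profile, summarized as the mean absolute residual — a measure of
  fine-grained precision.

Per-participant summaries (standardized within study) then enter a
hierarchical brain–behavior model for each network and task phase:

    activity_i = α_study(i) + β₁·z(θ′)_i + β₂·z(θb′)_i [+ β₃ interaction] + ε_i

with a random intercept per study — fit both by REML (Wald tests,
Benjamini–Hochberg FDR across the networks of interest, Cohen's *f*² from
marginal *R*²) and as a Bayesian two-level normal model (Normal(0, 10)
priors on coefficients, half-Cauchy(0, 2.5) on scales, posterior
probabilities of effect sign, R̂/ESS convergence checks). A participant-level
bootstrap traces how β estimates, effect sizes and FDR-corrected statistical
power change with sample size n.

A synthetic-data generator (`swmkit.synthdata`) emulates the whole
multi-study design with known ground truth — response noise SD σᵢ, diagonal
pull weight wᵢ, amplitude bias, filter-violating outliers, network activity
with known coefficients, and task-GLM time series — so every stage of the
pipeline is testable against its generative parameters.

## Worked example

```python
from swmkit import behavior, brainbehavior, synthdata

cfg = synthdata.GeneratorConfig(seed=1)          # 6 studies, 153 participants
trials, truths = synthdata.generate_dataset(cfg)
result = behavior.analyze(trials)                # decompose, filter, summarize

print(round(result.stats["pearson_r"], 3))
anova = result.stats["anova"]["pure_angular_error"]
print(anova["df1"], anova["df2"], round(anova["F"], 2))

activity, _ = synthdata.simulate_network_activity(truths, seed=1)
lmm = brainbehavior.run_phase_analysis(activity, result.summaries)
row = lmm.set_index(["network", "term"]).loc[
    ("dorsal-attention", "z_pure_angular_error")]
print(round(row["beta"], 3), round(row["q"], 4))
```

prints

```
0.537
5 147 0.44
-0.381 0.0003
```

i.e. participants with poorer fine-grained precision show more categorical
bias (r = 0.54 across 153 simulated participants); the between-study ANOVA
has (5, 147) degrees of freedom (F ≈ 0.4 here — the generator draws
participant parameters identically across studies, so there are no true
between-study differences); and the dorsal-attention network shows the
planted negative delay-activity association with pure angular error
(standardized β = −0.38, FDR-corrected q < 0.001 in this realization).

The same stages run from the shell:

```bash
swm simulate --out run1 --seed 1
swm behavior --out run1 --trials run1/trials.tsv
swm model    --out run1 --activity run1/activity.tsv --summaries run1/summaries.tsv
swm power    --out run1 --activity run1/activity.tsv --summaries run1/summaries.tsv --seed 1
```

or end-to-end from a YAML config with `swm run config.yaml`, which writes a
`manifest.json` of content hashes for reproducibility.

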