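# Methods

This note documents the models implemented in `swmkit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Behavioral decomposition

Angles are degrees, counter-clockwise, 0° at screen right; amplitudes are
degrees of visual angle (°va). Pixel input is converted first via an
explicit px-per-°va scale (`behavior.trials_from_pixels`); no screen-distance
geometry is modeled.

Per trial, with `wrap()` mapping into (−180°, 180°]:

- angular error `e = wrap(response_angle − target_angle)`;
- amplitude error `a = response_amp − target_amp` (positive = overshoot);
- `d = signed distance of the target from the nearest diagonal
  {45°, 135°, 225°, 315°}`, in [−45°, 45°];
- toward-diagonal error `t = −sign(d)·e` (positive = rotated toward the
  diagonal; defined 0 when d = 0).

**Filtering** is two-stage and its order is fixed. Stage 1 (validity
windows): |e| > 45° or amplitude outside 0.5–1.75× the target amplitude.
Stage 2 (robust fences), per participant on stage-1 survivors: values
outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], applied independently to angular and
amplitude errors. Quartiles use linear interpolation between order
statistics (the numpy default) so results are bit-reproducible. Fewer than
4 surviving trials skips stage 2 with a logged warning. Filters are
single-pass: fences are not re-estimated after removal.

**Bias estimation.** Amplitude bias = mean amplitude error. Angular bias is
estimated as the mean toward-diagonal error at each distinct |d| present in
the participant's surviving trials; pooling the four quadrants and the two
sides of each diagonal through the sign flip treats "distinct angle from
the nearest diagonal" as distinct |d|, which is exact for
quadrant-symmetric designs like the generator's. Targets exactly on a
diagonal (d = 0) contribute no bias bin and keep their raw error as the
pure error.

**Pure errors.** `pure_e = e + sign(d)·b(|d|)` (equivalently the
toward-frame residual mapped back); `pure_a = a − amplitude_bias`. By
construction the toward-frame residual has exactly zero mean within each
bin — the test suite checks this to 1e−10.

**Summaries.** Fine-grained precision = mean |pure_e| over surviving
trials: after bias subtraction the signed mean is ~0, so only a magnitude
summary is informative (the SD of signed residuals is available via
`metric="sd"`). Categorical bias = RMS of the bias profile across bins.
Participants whose bias RMSD deviates more than 3 sample SDs from the
across-participant mean are excluded in a single pass (no iteration; only
this measure by default). Measures are then z-scored within study over
non-excluded participants (sample SD, ddof = 1); a study with fewer than two
usable participants or a constant measure is an error, not a silent NaN.

The between-study one-way ANOVA (with generalized eta squared
ηG² = SSb/(SSb+SSw), which for a one-way between-subjects design equals
η²) is computed on the *unstandardized* measures: it quantifies the
between-study differences that motivate standardizing.

## Synthetic-data generator

The generator emulates the pooled six-study design and is the ground truth
for every recovery test. Defaults (one value per knob, chosen once):

| parameter | default | rationale |
|---|---|---|
| studies × participants | 24/31/26/11/24/37 (= 153) | the pooled multi-study roster |
| trials per participant | 60 | mid-range of the 20–80 across studies |
| target amplitude | 6, 6, 6, 7, 7, 7 °va | constant within study, site-typical eccentricities |
| target angles | 24 per study, evenly spaced within quadrants | pseudorandom non-cardinal sets; exact per-study sets are not public |
| cardinal guard band | 5° | "never on the cardinal axes" is unquantified |
| σᵢ (noise SD) | 1.5–5° | plausible joystick angular imprecision |
| wᵢ (pull weight) | 0–0.4 | yields single-digit-degree biases at |d| ≤ 35° |
| ρ(log σ, w) | +0.6 | reproduces the observed positive precision–bias correlation |
| amplitude bias aᵢ | −0.10–+0.05 | undershoot more common than overshoot |
| amplitude noise | 0.15 °va per ° of σᵢ | ties both noise sources to one latent precision; σ→0 gives exact responses |
| outlier probability | 0.08 | matches the reported single-digit trial-exclusion percentage |

Latent (log σᵢ, wᵢ) come from a correlated bivariate normal mapped through
the normal CDF onto their ranges, so one knob (ρ) controls the
precision–bias coupling. The pull is linear in |d| by default
(`g(|d|) = |d|`, matching bias that grows with distance from the diagonal);
a saturating form is available. Angle sequences are balanced permutations of
the study's angle set, so every |d| bin is populated. Outlier responses are
drawn to violate the filter windows (angle offset 46–180°, or amplitude
ratio in 0.20–0.45 / 1.80–2.50), so the filters must catch them.

Network activity is generated per participant and network as
`study intercept + β_PE·z(PE) + β_AB·z(AB) + β_int·z(PE)z(AB) + noise`
with z() of the *true* behavioral measures within study; defaults
β_PE = −0.25, β_AB = +0.25, study-intercept SD 0.5, noise SD 1 — effect
sizes of the order reported for delay-phase networks. The default network
map puts the negative precision effect in the three control/attention
networks and the positive bias effect in the default network.

What the generator does **not** emulate: between-study shifts in the
behavioral measures themselves (parameters are drawn identically across
studies, so the between-study ANOVA F is near 1 and only its degrees of
freedom are meaningful); serial dependence, learning or fatigue across
trials; non-Gaussian response noise; swap/guess trials; eye-movement or
cue-response behavior. Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed generative family, not
robustness to real-data violations of it.

## Task GLM

The double-gamma HRF uses the canonical parameterization (peak delay 6 s,
undershoot delay 16 s, unit dispersions, undershoot ratio 1/6, 32 s
support), normalized to peak 1; its mode on a 0.1 s grid is 5.0 s. Each task
phase (encoding, delay, response) pools its non-outlier trials into one
boxcar convolved at 16× oversampling and sampled at the TR. Trials flagged
as behavioral outliers get unassumed per-trial FIR banks (default order 8);
cue events, when present, share one pooled FIR bank. Nuisance columns:
6 motion parameters, their first derivatives and squares, an intercept and
a linear drift. Estimation is OLS with white noise — no prewhitening; at
desk scale with white simulated noise this is exact, and it is a documented
limitation for colored real noise. Rank-deficient designs are rejected with
the offending columns named (QR with pivoting).

Group stats: per unit, two-tailed one-sample t against 0 with BH-FDR across
units; zero-variance units give p = 1 if the mean is 0 and an error
otherwise. β-map participant outliers: distance 1 − r and RMSD of each
participant's β vector to the group mean vector, each z-scored; a
participant is flagged beyond +3 SD on either distance (only the
high/deviant side is abnormal).

## Brain–behavior models

The frequentist model is a random-intercept-by-study linear model on
within-study standardized activity with standardized fixed effects
(precision, bias, and their interaction by default — the interaction can be
switched off; effect sizes are reported for the main effects). Wald
(normal-approximation) two-tailed p-values are used deliberately: residual
df conventions for mixed models are unsettled, and at n ≈ 153 with 6
studies the normal approximation is near-nominal (measured type-I ≈ 0.052
at α = 0.05 in the calibration tests). Cohen's
f² = (R²_full − R²_reduced)/(1 − R²_full) uses the marginal (fixed-effects)
R² = var(Xβ)/(var(Xβ) + τ² + σ²); the reduced model drops only the focal
column. BH-FDR is applied across the four networks of interest within each
phase, separately per term (the multiple-comparison family is "networks";
whether phases were pooled is ambiguous, and per-phase families are the
conservative reading given phases are analyzed separately).

Two fitting engines expose the same model: statsmodels `MixedLM` (default)
and a profiled-REML scalar solver that concentrates out β and σ² and
optimizes the single variance ratio τ²/σ² by bounded search
(`engine="fast"`, used in the bootstrap's inner loop). They agree to ~1e−4
on β; the test suite cross-checks them, and the statsmodels path falls back
to the profiled solver when the default optimizer returns unusable boundary
SEs. Single-study data (or zero between-study variance) collapse to OLS
with the group variance pinned at 0; non-convergence is flagged on the
result, never raised.

One known reporting ambiguity in the literature this mirrors: a
response-phase control-network effect described as negative alongside a
printed positive coefficient; the package takes no side and simply reports
signed coefficients.

## Bayesian model

Same standardized data and design; varying intercepts by study
(α_s = μ_α + τ·η_s), Normal(0, 10) priors on coefficients and μ_α,
half-Cauchy(0, 2.5) on τ and σ. The sampler is a blocked Gibbs sweep: the
half-Cauchy priors are written as inverse-gamma scale mixtures so every
conditional is conjugate, and each sweep ends with an
ancillarity-sufficiency interweaving step that slice-samples τ in the
non-centered parameterization (η held fixed). The interweaving move targets
the same funnel degeneracy at small τ that the non-centered
parameterization addresses in gradient-based samplers; with within-study
standardized responses, τ is small and this matters. Defaults: 4 chains ×
1000 post-warmup draws after 1000 warmup sweeps, seeded per chain from the
global seed.

Convergence is assessed with rank-normalized split-R̂ and bulk/tail ESS
(arviz); the pass criterion is ESS > 400 (bulk and tail) for every reported
parameter and |R̂ − 1| ≤ 0.01 (the tolerance quantifies "does not deviate
from 1.0"). The derived η_s draws are excluded from the default diagnostic
set because they are undefined as τ → 0. Prior-only sampling (n = 0) is
supported and recovers the prior SD of the coefficients — a direct check
that the priors are what they claim. Posterior sign probabilities are the
fractions of draws strictly above/below zero; exact zeros count toward
neither.

At n = 153 with these weak priors, posterior means agree with REML
estimates to < 0.05 and widening the coefficient prior SD from 10 to 100
moves them by < 0.01 — both checked in the suite.

## Sample-size resampling

The resampling unit is the participant: each bootstrap draw takes n
participants with replacement, carrying their behavioral z-scores, study
label and all network activities together. Draws are redrawn until at least
two studies are represented (resamples that fail 100 redraws are recorded
as failed and skipped); non-convergent fits count as non-significant for
power. Per (n, network, term) the curve records the mean/min/max β,
equal-tailed empirical 95% and 99% bands across resamples, mean f², and
power = the proportion of resamples whose effect survives BH-FDR across the
network family at α = 0.05. The stabilization sample size is the smallest
grid n from which the 95% band excludes zero at that and every larger grid
point.

The desk-scale default is a grid of every 10th n from 15 (plus the full
sample) with B = 100 resamples per size; the full per-n grid with B = 1000
is a configuration choice, not a code change. Monte-Carlo tolerances in the
tests (isotonic-regression RMS < 0.05 for power monotonicity and band-width
shrinkage, binomial 2·SE bands for null calibration at 500 replications)
are fixed from the replication counts in advance.

## Determinism

All randomness flows from one root seed through named sub-streams
(stage : participant / chain / grid-point), so re-running any stage with
the same seed is byte-identical and toggling one stage never shifts
another's draws. The pipeline writes a manifest of SHA-256 content hashes;
the test suite asserts two orchestrated runs produce identical manifests
and that standalone stage runs reproduce the orchestrated outputs exactly.
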