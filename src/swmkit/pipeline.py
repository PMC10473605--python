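"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate -> behavior -> glm -> model -> bayes ->
power according to the stage toggles in a :class:`PipelineConfig`, writing
TSV outputs, a JSON manifest with content hashes, and a run log with
per-stage counts.  Every stage is also runnable standalone on the previous
stage's files, and the orchestrated run equals the standalone sequence
byte-for-byte under the same seeds: all randomness derives from the global
seed through named sub-streams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bayes, behavior, brainbehavior, resampling, synthdata, taskglm
from .io import SCHEMAS, file_sha256, read_table, write_table

logger = logging.getLogger("swmkit.pipeline")

__all__ = ["PipelineConfig", "run_pipeline",
           "stage_simulate", "stage_behavior", "stage_glm",
           "stage_model", "stage_bayes", "stage_power"]


@dataclass
class PipelineConfig:
    out_dir: str = "swm_out"
    seed: int = 0
    log_level: str = "INFO"
    stages: dict[str, bool] = field(default_factory=lambda: {
        "simulate": True, "behavior": True, "glm": False,
        "model": True, "bayes": False, "power": True,
    })
    simulate: dict[str, Any] = field(default_factory=dict)
    behavior: dict[str, Any] = field(default_factory=dict)
    glm: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    bayes: dict[str, Any] = field(default_factory=dict)
    power: dict[str, Any] = field(default_factory=dict)
    #: input paths used when the corresponding producer stage is disabled
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key '{key}'")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg


def _generator_config(params: dict[str, Any], seed: int) -> synthdata.GeneratorConfig:
    kwargs = dict(params)
    coeffs = kwargs.pop("activity_coeffs", None)
    for key in ("participants_per_study", "target_amplitude", "sigma_range",
                "w_range", "amp_bias_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    cfg = synthdata.GeneratorConfig(seed=seed, **kwargs)
    if coeffs is not None:
        cfg = synthdata.GeneratorConfig(
            **{**cfg.__dict__, "activity_coeffs":
               synthdata.ActivityCoeffs(**coeffs)}
        )
    return cfg


def stage_simulate(out: Path, params: dict[str, Any], seed: int) -> list[Path]:
    cfg = _generator_config(params, seed)
    trials, truths = synthdata.generate_dataset(cfg)
    activity, coeff_truth = synthdata.simulate_network_activity(
        truths, seed=seed
    )
    written = [
        write_table(trials, out / "trials.tsv", columns=SCHEMAS["trials"]),
        write_table(synthdata.truths_to_frame(truths), out / "truth.tsv"),
        write_table(activity, out / "activity.tsv"),
        write_table(coeff_truth, out / "activity_truth.tsv"),
    ]
    ts_params = params.get("timeseries")
    if ts_params:
        schedule = synthdata.make_event_schedule(ts_params.get("n_trials", 10))
        ts, _, _ = synthdata.simulate_timeseries(
            schedule,
            truths[: ts_params.get("n_participants", 4)],
            glm_truth=ts_params.get(
                "glm_truth", {"encoding": 1.0, "delay": 0.5, "response": 1.0}
            ),
            seed=seed,
            tr=ts_params.get("tr", 1.0),
            networks=ts_params.get("networks", ["network_1", "network_2"]),
            noise_sd=ts_params.get("noise_sd", 1.0),
        )
        written.append(write_table(schedule, out / "events.tsv"))
        written.append(write_table(ts, out / "timeseries.tsv"))
    logger.info("simulate: %d trials, %d participants",
                len(trials), len(truths))
    return written


def stage_behavior(out: Path, trials_path: Path,
                   params: dict[str, Any]) -> list[Path]:
    trials = read_table(trials_path, "trials")
    rules = behavior.FilterRules(
        angle_window=params.get("filter_angle_window", 45.0),
        amp_ratio_low=params.get("amp_ratio_low", 0.5),
        amp_ratio_high=params.get("amp_ratio_high", 1.75),
        iqr_k=params.get("iqr_k", 1.5),
    )
    result = behavior.analyze(
        trials, rules, participant_sd_k=params.get("participant_sd_k", 3.0)
    )
    n_excl = int(result.summaries["excluded"].sum())
    logger.info(
        "behavior: %.2f%% trials excluded on average, %d participants excluded",
        result.summaries["pct_trials_excluded"].mean(), n_excl,
    )
    return [
        write_table(result.errors, out / "errors.tsv"),
        write_table(result.profiles, out / "profiles.tsv"),
        write_table(result.summaries, out / "summaries.tsv"),
    ]


def stage_glm(out: Path, timeseries_path: Path, events_path: Path,
              params: dict[str, Any]) -> list[Path]:
    ts = read_table(timeseries_path, "timeseries")
    schedule = read_table(events_path, "events")
    tr = params.get("tr", 1.0)
    fir_order = params.get("fir_order", 8)
    n_frames = int(ts["frame"].max()) + 1
    design = taskglm.build_design_matrix(
        schedule, motion=None, tr=tr, n_frames=n_frames, fir_order=fir_order
    )
    rows = []
    for (pid, net), grp in ts.groupby(["participant_id", "network"]):
        y = grp.sort_values("frame")["value"].to_numpy()
        fit = taskglm.fit_glm(y, design)
        for phase in taskglm.PHASES:
            rows.append({"participant_id": pid, "network": net,
                         "phase": phase, "beta": fit.beta.get(phase, np.nan)})
    betas = pd.DataFrame(rows)
    written = [write_table(betas, out / "betas.tsv")]
    delay = betas[betas["phase"] == "delay"].pivot(
        index="participant_id", columns="network", values="beta"
    )
    if len(delay) >= 3 and delay.shape[1] >= 2:
        units, parts = taskglm.group_stats_and_outliers(delay)
        written.append(write_table(units, out / "groupstats.tsv"))
        written.append(write_table(parts, out / "beta_outliers.tsv"))
    logger.info("glm: fit %d participant x network series",
                ts.groupby(["participant_id", "network"]).ngroups)
    return written


def stage_model(out: Path, activity_path: Path, summaries_path: Path,
                params: dict[str, Any]) -> list[Path]:
    activity = read_table(activity_path, "activity")
    summaries = read_table(summaries_path, "summaries")
    spec = brainbehavior.LMMSpec(
        interaction=params.get("interaction", True),
        reml=params.get("reml", True),
    )
    results = brainbehavior.run_phase_analysis(
        activity, summaries, spec=spec, alpha=params.get("alpha", 0.05)
    )
    logger.info("model: %d (phase, network, term) results, %d significant",
                len(results), int(results["reject"].sum()))
    return [write_table(results, out / "lmm_results.tsv")]


def stage_bayes(out: Path, activity_path: Path, summaries_path: Path,
                params: dict[str, Any], seed: int) -> list[Path]:
    activity = read_table(activity_path, "activity")
    summaries = read_table(summaries_path, "summaries")
    data = brainbehavior.standardize_activity(activity, summaries)
    chains = params.get("chains", 4)
    draws = params.get("draws", 1000)
    warmup = params.get("warmup", draws)
    interaction = params.get("interaction", False)
    sign_rows, diag_rows, draw_frames = [], [], []
    for (phase, net), cell in data.groupby(["phase", "network"]):
        post = bayes.sample_posterior(
            cell, chains=chains, draws=draws, warmup=warmup,
            interaction=interaction, seed=seed,
        )
        diag = bayes.diagnose(post)
        for term in ("z_pure_angular_error", "z_angular_bias"):
            probs = bayes.sign_probability(post, term)
            sign_rows.append({"phase": phase, "network": net, "term": term,
                              "mean": float(post.flat(term).mean()), **probs})
        d = diag.table.copy()
        d.insert(0, "network", net)
        d.insert(0, "phase", phase)
        d["passed"] = diag.passed
        diag_rows.append(d)
        flat = pd.DataFrame({k: v.ravel() for k, v in post.params.items()
                             if not k.startswith(("alpha[", "eta["))})
        flat.insert(0, "network", net)
        flat.insert(0, "phase", phase)
        draw_frames.append(flat)
    logger.info("bayes: sampled %d models", len(draw_frames))
    return [
        write_table(pd.DataFrame(sign_rows), out / "sign_probs.tsv"),
        write_table(pd.concat(diag_rows, ignore_index=True),
                    out / "diagnostics.tsv"),
        write_table(pd.concat(draw_frames, ignore_index=True),
                    out / "draws.tsv"),
    ]


def stage_power(out: Path, activity_path: Path, summaries_path: Path,
                params: dict[str, Any], seed: int) -> list[Path]:
    activity = read_table(activity_path, "activity")
    summaries = read_table(summaries_path, "summaries")
    data = brainbehavior.standardize_activity(activity, summaries)
    networks = tuple(params.get(
        "networks",
        [n for n in brainbehavior.DEFAULT_FAMILY
         if n in set(data["network"])],
    ))
    wide = resampling.prepare_bootstrap_data(
        data, networks, phase=params.get("phase", "delay")
    )
    n_min = params.get("n_min", 15)
    n_max = params.get("n_max", len(wide))
    step = params.get("step", 10)
    grid = tuple(range(n_min, n_max + 1, step))
    curve = resampling.bootstrap_curve(
        wide, networks, grid,
        B=params.get("B", 100), alpha=params.get("alpha", 0.05), seed=seed,
        spec=brainbehavior.LMMSpec(interaction=params.get("interaction", True)),
        compute_f2=params.get("compute_f2", True),
    )
    stab = resampling.stabilization_n(curve)
    logger.info("power: %d grid points x %d resamples, %d failed",
                len(grid), curve.B, curve.n_failed)
    return [
        write_table(curve.table, out / "curve.tsv"),
        write_table(stab, out / "stabilization.tsv"),
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "swm.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("swmkit")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    seed = config.seed
    logger.info("pipeline start, seed=%d", seed)

    paths = {
        "trials": out / "trials.tsv",
        "activity": out / "activity.tsv",
        "summaries": out / "summaries.tsv",
        "timeseries": Path(config.inputs.get("timeseries", out / "timeseries.tsv")),
        "events": Path(config.inputs.get("events", out / "events.tsv")),
    }
    for key in ("trials", "activity", "summaries"):
        if key in config.inputs:
            paths[key] = Path(config.inputs[key])

    written: list[Path] = []

    def run_stage(name: str, fn, *args) -> None:
        if not config.stages.get(name, False):
            return
        produced: list[Path] = []
        try:
            produced = fn(*args)
            written.extend(produced)
        except Exception:
            for p in produced:
                Path(p).unlink(missing_ok=True)
            logger.exception("stage %s failed; partial outputs removed", name)
            raise

    run_stage("simulate", stage_simulate, out, config.simulate, seed)
    run_stage("behavior", stage_behavior, out, paths["trials"], config.behavior)
    run_stage("glm", stage_glm, out, paths["timeseries"], paths["events"],
              config.glm)
    run_stage("model", stage_model, out, paths["activity"],
              paths["summaries"], config.model)
    run_stage("bayes", stage_bayes, out, paths["activity"],
              paths["summaries"], config.bayes, seed)
    run_stage("power", stage_power, out, paths["activity"],
              paths["summaries"], config.power, seed)

    manifest = {
        "seed": seed,
        "files": {str(p.relative_to(out)): file_sha256(p)
                  for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline done: %d files", len(manifest["files"]))
    root.removeHandler(handler)
    handler.close()
    return manifest
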