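"""Behavioral decomposition of spatial working-memory responses.

Each joystick response is decomposed, in polar screen coordinates, into a
signed angular error and a signed amplitude error.  The angular error is
further split into a *categorical* component — the participant's systematic
bias toward the nearest quadrant diagonal, estimated as the mean
toward-diagonal error at each distinct target distance from the diagonal —
and a *fine-grained* component, the pure angular error remaining after that
systematic bias is subtracted.

Processing order is fixed: convert -> decompose -> window filters -> IQR
filters -> bias estimation -> pure errors -> participant summaries ->
participant exclusion -> within-study standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FilterRules",
    "BehaviorResult",
    "wrap_angle",
    "signed_diagonal_distance",
    "trials_from_pixels",
    "decompose_errors",
    "apply_trial_filters",
    "estimate_bias_profiles",
    "compute_pure_errors",
    "summarize_participants",
    "exclude_outlier_participants",
    "standardize_within_study",
    "one_way_anova",
    "correlate_and_compare",
    "analyze",
]

_KEYS = ["study_id", "participant_id"]


@dataclass(frozen=True)
class FilterRules:
    """Trial-level response filters.

    Stage 1 (windows): responses more than ``angle_window`` degrees from the
    target, or with amplitude outside ``[amp_ratio_low, amp_ratio_high]``
    times the target amplitude.  Stage 2 (robust): per participant, errors
    outside ``iqr_k`` interquartile ranges beyond the quartiles, applied
    independently to angular and amplitude errors of stage-1 survivors.
    """

    angle_window: float = 45.0
    amp_ratio_low: float = 0.5
    amp_ratio_high: float = 1.75
    iqr_k: float = 1.5
    min_trials_for_iqr: int = 4


def wrap_angle(x):
    """Wrap angles (deg) into the half-open interval (-180, 180]."""
    w = np.mod(np.asarray(x, dtype=float), 360.0)
    return np.where(w > 180.0, w - 360.0, w)


def signed_diagonal_distance(angle):
    """Signed distance (deg) of an angle from the nearest quadrant diagonal.

    Diagonals sit at 45/135/225/315 deg; the result lies in [-45, 45], with
    positive values counter-clockwise of the diagonal.
    """
    m = np.mod(np.asarray(angle, dtype=float) - 45.0, 90.0)
    return np.where(m > 45.0, m - 90.0, m)


def trials_from_pixels(
    df: pd.DataFrame,
    px_per_dva: float,
    center_x: float = 0.0,
    center_y: float = 0.0,
) -> pd.DataFrame:
    """Convert pixel-coordinate targets/responses to polar deg / deg-va.

    Expects columns ``target_x_px, target_y_px, response_x_px,
    response_y_px``; angles are measured counter-clockwise from screen right.
    """
    if px_per_dva <= 0:
        raise ValueError("px_per_dva must be positive")
    out = df.copy()
    for role in ("target", "response"):
        dx = (df[f"{role}_x_px"] - center_x) / px_per_dva
        dy = (df[f"{role}_y_px"] - center_y) / px_per_dva
        out[f"{role}_angle_deg"] = np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)
        out[f"{role}_amp_dva"] = np.hypot(dx, dy)
    return out


def decompose_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial polar error decomposition.

    Adds ``angular_error`` (deg, signed, in (-180, 180]), ``amplitude_error``
    (deg-va, positive = overshoot), ``d`` (signed target distance from the
    nearest diagonal), ``abs_d`` and ``toward_error`` (positive = response
    rotated from the target toward its nearest diagonal; 0 when d = 0).
    """
    required = [
        "target_angle_deg", "target_amp_dva",
        "response_angle_deg", "response_amp_dva",
    ]
    for col in required:
        if col not in trials.columns:
            raise ValueError(f"missing column '{col}' in trial table")
        if trials[col].isna().any():
            raise ValueError(f"missing values in '{col}'")
    if (trials["target_amp_dva"] <= 0).any():
        raise ValueError("target amplitude must be positive")

    out = trials.copy()
    out["angular_error"] = wrap_angle(
        out["response_angle_deg"].to_numpy() - out["target_angle_deg"].to_numpy()
    )
    out["amplitude_error"] = out["response_amp_dva"] - out["target_amp_dva"]
    d = signed_diagonal_distance(out["target_angle_deg"].to_numpy())
    out["d"] = d
    out["abs_d"] = np.round(np.abs(d), 6)
    out["toward_error"] = -np.sign(d) * out["angular_error"].to_numpy()
    return out


def apply_trial_filters(
    errors: pd.DataFrame, rules: FilterRules = FilterRules()
) -> pd.DataFrame:
    """Flag invalid and outlier trials; adds boolean flag columns.

    ``window_angle``/``window_amp`` implement the stage-1 windows;
    ``iqr_angle``/``iqr_amp`` the per-participant stage-2 robust fences
    (computed on stage-1 survivors with linear-interpolation quartiles).
    ``excluded`` is the union.  Participants with fewer than
    ``min_trials_for_iqr`` surviving trials skip stage 2 with a warning.
    """
    out = errors.copy()
    ratio = out["response_amp_dva"] / out["target_amp_dva"]
    out["window_angle"] = np.abs(out["angular_error"]) > rules.angle_window
    out["window_amp"] = (ratio < rules.amp_ratio_low) | (ratio > rules.amp_ratio_high)
    stage1 = ~(out["window_angle"] | out["window_amp"])

    out["iqr_angle"] = False
    out["iqr_amp"] = False
    for pid, idx in out.groupby("participant_id").groups.items():
        surv = out.loc[idx][stage1.loc[idx]]
        if len(surv) < rules.min_trials_for_iqr:
            logger.warning(
                "participant %s: %d surviving trials < %d, IQR stage skipped",
                pid, len(surv), rules.min_trials_for_iqr,
            )
            continue
        for col, flag in (("angular_error", "iqr_angle"),
                          ("amplitude_error", "iqr_amp")):
            q1, q3 = np.percentile(surv[col], [25, 75], method="linear")
            lo = q1 - rules.iqr_k * (q3 - q1)
            hi = q3 + rules.iqr_k * (q3 - q1)
            bad = surv.index[(surv[col] < lo) | (surv[col] > hi)]
            out.loc[bad, flag] = True
    out["excluded"] = (
        out["window_angle"] | out["window_amp"] | out["iqr_angle"] | out["iqr_amp"]
    )
    return out


def participant_exclusion_rates(flagged: pd.DataFrame) -> pd.Series:
    """Percentage of trials excluded per participant."""
    return flagged.groupby("participant_id")["excluded"].mean() * 100.0


def estimate_bias_profiles(
    flagged: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Systematic bias estimates per participant, from unflagged trials only.

    Returns ``(profiles, amp_bias)``: ``profiles`` has one row per
    participant x distinct |d| bin with the mean toward-diagonal error
    (positive = toward) and trial count; ``amp_bias`` one row per
    participant with the mean amplitude error (negative = undershoot).
    Targets exactly on a diagonal (d = 0) contribute no bias bin.
    """
    good = flagged[~flagged["excluded"]]
    amp_bias = (
        good.groupby(_KEYS, as_index=False)["amplitude_error"]
        .mean()
        .rename(columns={"amplitude_error": "amplitude_bias"})
    )
    binned = good[good["abs_d"] > 0]
    profiles = (
        binned.groupby(_KEYS + ["abs_d"], as_index=False)
        .agg(bias_deg=("toward_error", "mean"), n_trials=("toward_error", "size"))
    )
    return profiles, amp_bias


def compute_pure_errors(
    flagged: pd.DataFrame, profiles: pd.DataFrame, amp_bias: pd.DataFrame
) -> pd.DataFrame:
    """Subtract systematic biases from trialwise errors.

    ``pure_angular_error = angular_error + sign(d) * b(|d|)`` (equivalently
    the toward-diagonal residual re-expressed in the original angular
    frame); trials at d = 0 keep their raw angular error.
    ``pure_amplitude_error = amplitude_error - amplitude_bias``.  Pure
    fields are NaN on excluded trials.
    """
    out = flagged.merge(
        profiles[_KEYS + ["abs_d", "bias_deg"]], on=_KEYS + ["abs_d"], how="left"
    ).merge(amp_bias, on=_KEYS, how="left")
    missing = (~out["excluded"]) & (out["abs_d"] > 0) & out["bias_deg"].isna()
    if missing.any():
        raise ValueError(
            "trials at |d| bins absent from the bias profile: "
            f"{out.loc[missing, 'participant_id'].unique().tolist()}"
        )
    b = out["bias_deg"].fillna(0.0)
    out["pure_angular_error"] = out["angular_error"] + np.sign(out["d"]) * b
    out["pure_amplitude_error"] = out["amplitude_error"] - out["amplitude_bias"]
    out.loc[out["excluded"], ["pure_angular_error", "pure_amplitude_error"]] = np.nan
    return out.drop(columns=["bias_deg"])


def summarize_participants(
    pure: pd.DataFrame,
    profiles: pd.DataFrame,
    amp_bias: pd.DataFrame,
    metric: str = "mean_abs",
) -> pd.DataFrame:
    """Per-participant summary measures.

    ``pure_angular_error`` is the mean absolute pure angular error over
    surviving trials (``metric='sd'`` switches to the SD of signed pure
    errors); ``angular_bias_rmsd`` is the root-mean-square of the bias
    profile across |d| bins.  Participants with no surviving trials are
    marked excluded.
    """
    if metric not in ("mean_abs", "sd"):
        raise ValueError("metric must be 'mean_abs' or 'sd'")
    roster = pure[_KEYS].drop_duplicates().reset_index(drop=True)
    good = pure[~pure["excluded"]]
    if metric == "mean_abs":
        pe = good.groupby("participant_id")["pure_angular_error"].apply(
            lambda x: np.mean(np.abs(x))
        )
    else:
        pe = good.groupby("participant_id")["pure_angular_error"].std(ddof=1)
    rmsd = profiles.groupby("participant_id")["bias_deg"].apply(
        lambda b: float(np.sqrt(np.mean(np.square(b))))
    )
    pct = pure.groupby("participant_id")["excluded"].mean() * 100.0
    n_surv = good.groupby("participant_id").size()

    out = roster.copy()
    out["pure_angular_error"] = out["participant_id"].map(pe)
    out["angular_bias_rmsd"] = out["participant_id"].map(rmsd)
    out["amplitude_bias"] = out["participant_id"].map(
        amp_bias.set_index("participant_id")["amplitude_bias"]
    )
    out["n_trials_surviving"] = (
        out["participant_id"].map(n_surv).fillna(0).astype(int)
    )
    out["pct_trials_excluded"] = out["participant_id"].map(pct).fillna(100.0)
    out["excluded"] = out["n_trials_surviving"] == 0
    return out


def exclude_outlier_participants(
    summaries: pd.DataFrame,
    k: float = 3.0,
    measures: tuple[str, ...] = ("angular_bias_rmsd",),
) -> pd.DataFrame:
    """Single-pass k x SD participant exclusion (default: bias RMSD only).

    Flags participants whose measure deviates more than ``k`` sample SDs
    from the across-participant mean.  Zero SD, or ``k = inf``, excludes
    nobody.  Flagging is done once, not iterated.
    """
    if len(summaries) < 3:
        raise ValueError("participant outlier exclusion needs >= 3 participants")
    out = summaries.copy()
    if not np.isfinite(k):
        return out
    for col in measures:
        x = out.loc[~out["excluded"], col]
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        dev = np.abs(out[col] - x.mean()) > k * sd
        out["excluded"] = out["excluded"] | dev.fillna(True)
    return out


def standardize_within_study(
    summaries: pd.DataFrame,
    measures: tuple[str, ...] = ("pure_angular_error", "angular_bias_rmsd"),
) -> pd.DataFrame:
    """Within-study z-scores over non-excluded participants (ddof = 1).

    Adds ``z_pure_angular_error`` and ``z_angular_bias`` (and analogous
    ``z_*`` columns for any extra measures); excluded participants get NaN.
    A study with fewer than two non-excluded participants, or a constant
    measure, is an error.
    """
    zname = {
        "pure_angular_error": "z_pure_angular_error",
        "angular_bias_rmsd": "z_angular_bias",
    }
    out = summaries.copy()
    for col in measures:
        zcol = zname.get(col, f"z_{col}")
        out[zcol] = np.nan
        for study, grp in out[~out["excluded"]].groupby("study_id"):
            if len(grp) < 2:
                raise ValueError(
                    f"study {study}: fewer than 2 non-excluded participants"
                )
            sd = grp[col].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"study {study}: '{col}' has zero variance")
            out.loc[grp.index, zcol] = (grp[col] - grp[col].mean()) / sd
    return out


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> dict:
    """Between-group one-way ANOVA with generalized eta squared.

    For a one-way between-subjects design the generalized eta squared equals
    SS_between / (SS_between + SS_within).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    grand = values.mean()
    ss_b = sum(
        (values[groups == g]).size * (values[groups == g].mean() - grand) ** 2
        for g in labels
    )
    ss_w = sum(
        np.sum((values[groups == g] - values[groups == g].mean()) ** 2)
        for g in labels
    )
    df1 = labels.size - 1
    df2 = values.size - labels.size
    if df2 <= 0 or ss_w == 0:
        raise ValueError("ANOVA degenerate: no within-group variance")
    F = (ss_b / df1) / (ss_w / df2)
    return {
        "F": float(F),
        "df1": int(df1),
        "df2": int(df2),
        "p": float(stats.f.sf(F, df1, df2)),
        "etaG2": float(ss_b / (ss_b + ss_w)),
    }


def correlate_and_compare(summaries: pd.DataFrame) -> dict:
    """Cross-measure Pearson correlation and between-study ANOVAs.

    The correlation is computed on the within-study z-scores; the ANOVAs on
    the unstandardized measures (they quantify the between-study
    differences that motivate standardizing in the first place).
    """
    good = summaries[~summaries["excluded"]]
    if len(good) < 3:
        raise ValueError("need >= 3 non-excluded participants")
    r, p = stats.pearsonr(good["z_pure_angular_error"], good["z_angular_bias"])
    result = {"pearson_r": float(r), "r_pvalue": float(p), "anova": {}}
    for col in ("pure_angular_error", "angular_bias_rmsd"):
        result["anova"][col] = one_way_anova(
            good[col].to_numpy(), good["study_id"].to_numpy()
        )
    return result


@dataclass
class BehaviorResult:
    """Outputs of the full behavioral analysis, in processing order."""

    errors: pd.DataFrame      # trialwise errors, flags and pure errors
    profiles: pd.DataFrame    # per-participant bias-by-|d| profiles
    amp_bias: pd.DataFrame    # per-participant amplitude bias
    summaries: pd.DataFrame   # participant summaries with z-scores
    stats: dict = field(default_factory=dict)


def analyze(
    trials: pd.DataFrame,
    rules: FilterRules = FilterRules(),
    participant_sd_k: float = 3.0,
    metric: str = "mean_abs",
    with_stats: bool = True,
) -> BehaviorResult:
    """Run the full fixed-order behavioral pipeline on a trial table."""
    errors = decompose_errors(trials)
    flagged = apply_trial_filters(errors, rules)
    profiles, amp_bias = estimate_bias_profiles(flagged)
    pure = compute_pure_errors(flagged, profiles, amp_bias)
    summaries = summarize_participants(pure, profiles, amp_bias, metric=metric)
    summaries = exclude_outlier_participants(summaries, k=participant_sd_k)
    summaries = standardize_within_study(summaries)
    stats_out = correlate_and_compare(summaries) if with_stats else {}
    return BehaviorResult(pure, profiles, amp_bias, summaries, stats_out)
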