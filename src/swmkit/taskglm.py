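"""Minimal per-phase task GLM for network time series.

Design matrices pool the encoding, delay and response phases of non-outlier
trials into one boxcar regressor each, convolved with the canonical
double-gamma hemodynamic response function.  Trials flagged as behavioral
outliers are modeled with unassumed finite-impulse-response (FIR) banks so
their shape is absorbed without an assumed response.  Nuisance columns are
the six motion parameters, their first derivatives and squares, plus an
intercept and a linear drift.  Estimation is ordinary least squares with a
white-noise error model (no prewhitening) — adequate for the synthetic
validation this module targets, and documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .brainbehavior import fdr_bh

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "double_gamma_hrf",
    "validate_schedule",
    "build_design_matrix",
    "fit_glm",
    "group_stats_and_outliers",
]

PHASES = ("encoding", "delay", "response")


@dataclass
class DesignMatrix:
    matrix: np.ndarray        # frame x regressor
    names: list[str]
    tr: float
    n_frames: int

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class GLMFit:
    beta: dict[str, float]
    sigma2: float
    dof: int


def double_gamma_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt`` seconds, peak scaled to 1.

    ``h(t) = g(t; peak) - ratio * g(t; undershoot)`` with gamma-density
    components parameterized by their delay (shape*scale) and dispersion
    (scale).  Defaults peak near 5 s with a late undershoot.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for v in (peak_delay, undershoot_delay, peak_disp, undershoot_disp, length):
        if v <= 0:
            raise ValueError("HRF parameters must be positive")
    t = np.arange(0.0, length, dt)
    h = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    if ratio != 0:
        h = h - ratio * stats.gamma.pdf(
            t, undershoot_delay / undershoot_disp, scale=undershoot_disp
        )
    return h / np.max(h)


def validate_schedule(schedule: pd.DataFrame, tr: float, n_frames: int) -> None:
    """Check event-schedule invariants: ordering, durations, scan bounds."""
    for phase in PHASES:
        if f"{phase}_onset" not in schedule or f"{phase}_duration" not in schedule:
            raise ValueError(f"schedule missing {phase} onset/duration")
        if (schedule[f"{phase}_duration"] <= 0).any():
            raise ValueError(f"{phase} durations must be positive")
    ends = schedule["response_onset"] + schedule["response_duration"]
    if (ends > tr * n_frames).any():
        raise ValueError("schedule extends past the scan duration")
    for a, b in (("encoding", "delay"), ("delay", "response")):
        if (schedule[f"{b}_onset"] < schedule[f"{a}_onset"]).any():
            raise ValueError("phase onsets must be non-decreasing within trial")
    # overlapping events of the same regressor are rejected
    for phase in PHASES:
        on = schedule[f"{phase}_onset"].to_numpy()
        off = on + schedule[f"{phase}_duration"].to_numpy()
        order = np.argsort(on)
        if np.any(on[order][1:] < off[order][:-1] - 1e-9):
            raise ValueError(f"overlapping {phase} events")


def _convolved_boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    tr: float,
    n_frames: int,
    oversample: int = 16,
) -> np.ndarray:
    dt = tr / oversample
    n_fine = n_frames * oversample
    box = np.zeros(n_fine)
    for on, dur in zip(onsets, durations):
        i0 = int(round(on / dt))
        i1 = int(round((on + dur) / dt))
        box[i0:min(i1, n_fine)] = 1.0
    conv = np.convolve(box, double_gamma_hrf(dt))[:n_fine]
    return conv[::oversample]


def build_design_matrix(
    schedule: pd.DataFrame,
    motion: np.ndarray | None,
    tr: float,
    n_frames: int,
    fir_order: int = 8,
    oversample: int = 16,
) -> DesignMatrix:
    """Assemble the frame x regressor design matrix.

    One HRF-convolved boxcar per phase pools the non-outlier trials; each
    outlier trial gets its own FIR bank of ``fir_order`` unit impulses at
    successive frames from its encoding onset; cue events (optional
    ``cue_onset`` column) share one pooled FIR bank.  Motion (frame x 6)
    expands to 18 nuisance columns; intercept and linear drift complete the
    baseline.  Raises on rank deficiency, naming the offending columns.
    """
    if len(schedule):
        validate_schedule(schedule, tr, n_frames)
        is_out = schedule["outlier"].to_numpy().astype(bool) \
            if "outlier" in schedule else np.zeros(len(schedule), bool)
    else:
        is_out = np.zeros(0, dtype=bool)

    cols: list[np.ndarray] = []
    names: list[str] = []
    keep = schedule[~is_out] if len(schedule) else schedule
    if len(keep):
        for phase in PHASES:
            cols.append(
                _convolved_boxcar(
                    keep[f"{phase}_onset"].to_numpy(),
                    keep[f"{phase}_duration"].to_numpy(),
                    tr, n_frames, oversample,
                )
            )
            names.append(phase)

    for _, row in schedule[is_out].iterrows():
        base = int(round(row["encoding_onset"] / tr))
        for j in range(fir_order):
            col = np.zeros(n_frames)
            if base + j < n_frames:
                col[base + j] = 1.0
            cols.append(col)
            names.append(f"outlier{int(row['trial'])}_fir{j}")
    if "cue_onset" in schedule and schedule["cue_onset"].notna().any():
        onsets = schedule.loc[schedule["cue_onset"].notna(), "cue_onset"]
        for j in range(fir_order):
            col = np.zeros(n_frames)
            for on in onsets:
                k = int(round(on / tr)) + j
                if k < n_frames:
                    col[k] += 1.0
            cols.append(col)
            names.append(f"cue_fir{j}")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_frames, 6):
            raise ValueError("motion must be frame x 6")
        deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
        for block, tag in ((motion, "mot"), (deriv, "dmot"), (motion**2, "mot2")):
            for j in range(6):
                cols.append(block[:, j])
                names.append(f"{tag}{j}")
    cols.append(np.ones(n_frames))
    names.append("intercept")
    cols.append(np.linspace(-0.5, 0.5, n_frames))
    names.append("drift")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R, piv = _qr_pivot(X)
        bad = [names[piv[i]] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    return DesignMatrix(X, names, tr, n_frames)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def fit_glm(y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares fit of one frame series against the design."""
    y = np.asarray(y, dtype=float)
    X = design.matrix
    if y.shape[0] != design.n_frames:
        raise ValueError("series length must equal the design frame count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.shape[0] - rank
    sigma2 = float(resid @ resid / dof) if dof > 0 else float("nan")
    return GLMFit(dict(zip(design.names, beta)), sigma2, dof)


def group_stats_and_outliers(
    betas: pd.DataFrame, k: float = 3.0, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level one-sample tests per unit and beta-map participant outliers.

    ``betas``: wide table, rows = participants, columns = units (parcels or
    networks).  Per unit: two-tailed one-sample t vs 0 with BH-FDR q across
    units (zero-variance units: p = 1 when the mean is 0, error otherwise).
    Per participant: Pearson correlation (as distance 1 - r) and RMSD of
    their beta vector to the group-average vector, z-scored; participants
    beyond ``k`` SD on either distance are flagged.
    """
    if len(betas) < 3:
        raise ValueError("group stats need >= 3 participants")
    t_rows = []
    for unit in betas.columns:
        x = betas[unit].to_numpy(dtype=float)
        if np.allclose(x.std(ddof=1), 0.0):
            if np.allclose(x.mean(), 0.0):
                t_rows.append({"unit": unit, "mean": 0.0, "t": 0.0, "p": 1.0})
                continue
            raise ValueError(f"unit {unit}: zero variance with nonzero mean")
        t, p = stats.ttest_1samp(x, 0.0)
        t_rows.append({"unit": unit, "mean": x.mean(), "t": float(t), "p": float(p)})
    units = pd.DataFrame(t_rows)
    q, reject = fdr_bh(units["p"].to_numpy(), alpha=alpha)
    units["q"] = q
    units["reject"] = reject

    group_mean = betas.mean(axis=0).to_numpy()
    B = betas.to_numpy(dtype=float)
    corr = np.array([np.corrcoef(row, group_mean)[0, 1] for row in B])
    rmsd = np.sqrt(np.mean((B - group_mean) ** 2, axis=1))
    parts = pd.DataFrame(
        {"participant": betas.index, "corr_dist": 1.0 - corr, "rmsd": rmsd}
    )
    for col in ("corr_dist", "rmsd"):
        sd = parts[col].std(ddof=1)
        parts[f"z_{col}"] = 0.0 if sd == 0 else (parts[col] - parts[col].mean()) / sd
    parts["outlier"] = (parts["z_corr_dist"] > k) | (parts["z_rmsd"] > k)
    return units, parts
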