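"""Synthetic multi-study spatial working-memory data with known ground truth.

The generator emulates a delayed-response joystick task pooled over several
fMRI studies: targets appear at a constant amplitude and pseudorandom
non-cardinal angles, and each response is the target plus a participant-
specific categorical pull toward the nearest quadrant diagonal plus Gaussian
motor/memory noise.  Per-participant network activity is then generated as a
linear function of the standardized true behavioral measures with study
intercepts, and network time series as a task GLM forward model.

Ground truth (noise SD ``sigma_i``, diagonal pull weight ``w_i``, amplitude
bias ``a_i``) is returned for every participant so that recovery of the
behavioral decomposition can be tested directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._seeds import child_rng

__all__ = [
    "ActivityCoeffs",
    "GeneratorConfig",
    "ParticipantTruth",
    "DEFAULT_NETWORKS",
    "study_target_angles",
    "generate_dataset",
    "simulate_network_activity",
    "simulate_timeseries",
    "make_event_schedule",
]

#: Networks of interest: three task-positive control/attention systems and
#: the task-negative default network.
DEFAULT_NETWORKS = (
    "cingulo-opercular",
    "dorsal-attention",
    "frontoparietal",
    "default",
)

_DIAGONALS = np.array([45.0, 135.0, 225.0, 315.0])


@dataclass(frozen=True)
class ActivityCoeffs:
    """Generative coefficients for per-participant network activity.

    Activity is ``study_intercept + beta_PE*z(PE) + beta_AB*z(AB)
    + beta_interaction*z(PE)*z(AB) + Normal(0, noise_sd**2)`` where z()
    standardizes the true behavioral measures within study.
    """

    beta_PE: float = -0.25
    beta_AB: float = 0.25
    beta_interaction: float = 0.0
    study_intercept_sd: float = 0.5
    noise_sd: float = 1.0

    def validate(self) -> None:
        for name in ("beta_PE", "beta_AB", "beta_interaction",
                     "study_intercept_sd", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"activity coefficient {name} must be finite")
        if self.study_intercept_sd < 0 or self.noise_sd < 0:
            raise ValueError("SD coefficients must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and generative parameters for the behavioral simulator.

    Defaults mirror the pooled six-study design: 153 participants split
    24/31/26/11/24/37 across studies, 60 trials each, targets at a constant
    per-study amplitude and evenly spaced non-cardinal angles.
    """

    n_studies: int = 6
    participants_per_study: tuple[int, ...] = (24, 31, 26, 11, 24, 37)
    trials_per_participant: int = 60
    #: constant target amplitude per study, degrees of visual angle
    target_amplitude: tuple[float, ...] = (6.0, 6.0, 6.0, 7.0, 7.0, 7.0)
    n_target_angles: int = 24
    #: no target within this band (deg) of the cardinal axes 0/90/180/270
    guard_band_deg: float = 5.0
    #: bounds of the fine-grained response noise SD sigma_i, degrees
    sigma_range: tuple[float, float] = (1.5, 5.0)
    #: bounds of the diagonal pull weight w_i (deg of pull per deg of |d|)
    w_range: tuple[float, float] = (0.0, 0.4)
    #: latent correlation between log-noise and pull weight
    rho_w_sigma: float = 0.6
    #: proportional amplitude bias a_i bounds (negative = undershoot)
    amp_bias_range: tuple[float, float] = (-0.10, 0.05)
    #: amplitude noise SD per degree of angular noise SD (deg-va / deg)
    amp_noise_ratio: float = 0.15
    #: probability a response is replaced by a filter-violating outlier
    outlier_prob: float = 0.08
    #: pull shape g(|d|): "linear" (g=|d|) or "saturating"
    pull_shape: str = "linear"
    #: saturation scale (deg) for the saturating pull form
    pull_scale: float = 30.0
    activity_coeffs: ActivityCoeffs = field(default_factory=ActivityCoeffs)
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies <= 0 or self.trials_per_participant <= 0:
            raise ValueError("counts must be positive")
        if len(self.participants_per_study) != self.n_studies:
            raise ValueError("participants_per_study length must equal n_studies")
        if any(n <= 0 for n in self.participants_per_study):
            raise ValueError("participant counts must be positive")
        if len(self.target_amplitude) != self.n_studies:
            raise ValueError("target_amplitude must give one value per study")
        if any(a <= 0 for a in self.target_amplitude):
            raise ValueError("target amplitudes must be positive")
        if self.n_target_angles <= 0:
            raise ValueError("n_target_angles must be positive")
        if self.sigma_range[0] <= 0 or self.sigma_range[1] < self.sigma_range[0]:
            raise ValueError("sigma_range must satisfy 0 < lo <= hi")
        if not (0.0 <= self.w_range[0] <= self.w_range[1] <= 1.0):
            raise ValueError("w_range must lie within [0, 1]")
        if abs(self.rho_w_sigma) > 1.0:
            raise ValueError("|rho_w_sigma| must be <= 1")
        if not (0.0 <= self.outlier_prob <= 1.0):
            raise ValueError("outlier_prob must be a probability")
        if self.guard_band_deg < 0 or self.guard_band_deg >= 45.0:
            raise ValueError(
                "guard band must be in [0, 45) deg or no legal angles remain"
            )
        if self.pull_shape not in ("linear", "saturating"):
            raise ValueError("pull_shape must be 'linear' or 'saturating'")


@dataclass(frozen=True)
class ParticipantTruth:
    """Generative ground truth for one participant."""

    study_id: str
    participant_id: str
    sigma: float            # response noise SD, deg
    w: float                # diagonal pull weight, dimensionless
    amp_bias: float         # proportional amplitude bias
    z_sigma: float          # latent standard-normal score behind sigma
    z_w: float              # latent standard-normal score behind w
    pe_true: float          # expected mean absolute pure angular error, deg
    ab_true: float          # expected angular-bias RMSD, deg


def study_target_angles(n_angles: int, guard_band_deg: float = 5.0) -> np.ndarray:
    """Evenly spaced target angles avoiding the cardinal axes.

    Angles are placed symmetrically within each quadrant, none closer than
    ``guard_band_deg`` to 0/90/180/270 deg.  Raises if the guard band leaves
    no legal angles.
    """
    if guard_band_deg >= 45.0:
        raise ValueError("guard band leaves no legal target angles")
    per_quadrant = [n_angles // 4] * 4
    for q in range(n_angles % 4):
        per_quadrant[q] += 1
    span = 90.0 - 2.0 * guard_band_deg
    angles = []
    for q, k in enumerate(per_quadrant):
        if k == 0:
            continue
        start = q * 90.0 + guard_band_deg
        angles.extend(start + (np.arange(k) + 0.5) * span / k)
    return np.sort(np.asarray(angles))


def _signed_diag_distance(angle: np.ndarray) -> np.ndarray:
    """Signed distance (deg) from the nearest quadrant diagonal, in [-45, 45]."""
    m = np.mod(np.asarray(angle, dtype=float) - 45.0, 90.0)
    return np.where(m > 45.0, m - 90.0, m)


def _pull_magnitude(abs_d: np.ndarray, shape: str, scale: float) -> np.ndarray:
    if shape == "linear":
        return abs_d
    # saturating: approaches `scale` for targets far from the diagonal
    return scale * (1.0 - np.exp(-abs_d / scale))


def _latent_to_range(z: np.ndarray, lo: float, hi: float, log: bool) -> np.ndarray:
    u = norm.cdf(z)
    if log:
        return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    return lo + u * (hi - lo)


def _expected_ab(w: float, abs_d_bins: np.ndarray, shape: str, scale: float) -> float:
    g = _pull_magnitude(abs_d_bins, shape, scale)
    return float(w * np.sqrt(np.mean(g**2)))


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[ParticipantTruth]]:
    """Simulate the trial table and per-participant ground truth.

    Returns a tidy trial table (one row per trial) and the list of
    :class:`ParticipantTruth`.  The extra boolean column ``planted_outlier``
    marks trials whose response was replaced by a filter-violating draw.
    """
    config.validate()
    angles = study_target_angles(config.n_target_angles, config.guard_band_deg)
    abs_d_bins = np.unique(np.round(np.abs(_signed_diag_distance(angles)), 6))
    abs_d_bins = abs_d_bins[abs_d_bins > 0]

    sig_lo, sig_hi = config.sigma_range
    w_lo, w_hi = config.w_range
    rho = config.rho_w_sigma
    n_trials = config.trials_per_participant

    rows: list[pd.DataFrame] = []
    truths: list[ParticipantTruth] = []
    for s in range(config.n_studies):
        study_id = f"S{s + 1}"
        amp = float(config.target_amplitude[s])
        for p in range(config.participants_per_study[s]):
            pid = f"{study_id}-P{p + 1:02d}"
            rng = child_rng(config.seed, "trials", study_id, pid)

            z1 = rng.standard_normal()
            z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal()
            sigma = float(_latent_to_range(np.array(z1), sig_lo, sig_hi, log=True))
            w = float(_latent_to_range(np.array(z2), w_lo, w_hi, log=False))
            a_i = float(rng.uniform(*config.amp_bias_range))

            # balanced pseudorandom angle sequence: every target angle is
            # visited before any repeats, so all |d| bins are populated
            reps = int(np.ceil(n_trials / angles.size))
            seq = np.concatenate([rng.permutation(angles) for _ in range(reps)])
            target = seq[:n_trials]
            d = _signed_diag_distance(target)
            pull = -np.sign(d) * w * _pull_magnitude(
                np.abs(d), config.pull_shape, config.pull_scale
            )
            resp_angle = target + pull + rng.normal(0.0, sigma, n_trials)
            resp_amp = amp * (1.0 + a_i) + rng.normal(
                0.0, config.amp_noise_ratio * sigma, n_trials
            )
            resp_amp = np.maximum(resp_amp, 0.0)

            is_outlier = rng.random(n_trials) < config.outlier_prob
            if is_outlier.any():
                k = int(is_outlier.sum())
                kind = rng.integers(0, 2, k)  # 0: angle violation, 1: amplitude
                off = rng.uniform(46.0, 180.0, k) * rng.choice([-1.0, 1.0], k)
                ratio = np.where(
                    rng.random(k) < 0.5,
                    rng.uniform(0.20, 0.45, k),
                    rng.uniform(1.80, 2.50, k),
                )
                oa = resp_angle[is_outlier].copy()
                om = resp_amp[is_outlier].copy()
                oa[kind == 0] = target[is_outlier][kind == 0] + off[kind == 0]
                om[kind == 1] = amp * ratio[kind == 1]
                resp_angle[is_outlier] = oa
                resp_amp[is_outlier] = om

            rows.append(
                pd.DataFrame(
                    {
                        "study_id": study_id,
                        "participant_id": pid,
                        "trial": np.arange(n_trials),
                        "target_angle_deg": target,
                        "target_amp_dva": amp,
                        "response_angle_deg": np.mod(resp_angle, 360.0),
                        "response_amp_dva": resp_amp,
                        "planted_outlier": is_outlier,
                    }
                )
            )
            truths.append(
                ParticipantTruth(
                    study_id=study_id,
                    participant_id=pid,
                    sigma=sigma,
                    w=w,
                    amp_bias=a_i,
                    z_sigma=float(z1),
                    z_w=float(z2),
                    pe_true=sigma * math.sqrt(2.0 / math.pi),
                    ab_true=_expected_ab(
                        w, abs_d_bins, config.pull_shape, config.pull_scale
                    ),
                )
            )
    trials = pd.concat(rows, ignore_index=True)
    return trials, truths


def truths_to_frame(truths: Sequence[ParticipantTruth]) -> pd.DataFrame:
    """Tidy per-participant ground-truth table."""
    return pd.DataFrame([t.__dict__ for t in truths])


def _zscore_within_study(df: pd.DataFrame, col: str) -> pd.Series:
    def z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant '{col}' within study")
        return (x - x.mean()) / sd

    return df.groupby("study_id", group_keys=False)[col].apply(z)


def simulate_network_activity(
    truths: Sequence[ParticipantTruth],
    coeffs: ActivityCoeffs | Mapping[str, ActivityCoeffs] | None = None,
    seed: int = 0,
    networks: Sequence[str] | None = None,
    phase: str = "delay",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-participant network activity from true behavioral measures.

    ``coeffs`` may be a single :class:`ActivityCoeffs` (applied to every
    network) or a mapping network -> coefficients.  When omitted, a
    domain-typical default is used: the three control/attention networks
    carry a negative pure-angular-error effect and the default network a
    positive angular-bias effect.

    Returns ``(activity, truth_coeffs)`` where ``activity`` has one row per
    participant x network and ``truth_coeffs`` records the generative
    coefficients alongside.
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    if coeffs is None:
        coeffs = {
            "cingulo-opercular": ActivityCoeffs(beta_PE=-0.25, beta_AB=0.0),
            "dorsal-attention": ActivityCoeffs(beta_PE=-0.25, beta_AB=0.0),
            "frontoparietal": ActivityCoeffs(beta_PE=-0.25, beta_AB=0.0),
            "default": ActivityCoeffs(beta_PE=0.0, beta_AB=0.25),
        }
    if isinstance(coeffs, ActivityCoeffs):
        if networks is None:
            networks = DEFAULT_NETWORKS
        coeffs = {net: coeffs for net in networks}
    else:
        networks = list(coeffs.keys())
    for c in coeffs.values():
        c.validate()

    tdf = truths_to_frame(truths)
    tdf["z_pe"] = _zscore_within_study(tdf, "pe_true")
    tdf["z_ab"] = _zscore_within_study(tdf, "ab_true")
    study_ids = sorted(tdf["study_id"].unique())

    frames = []
    truth_rows = []
    for net in networks:
        c = coeffs[net]
        icp_rng = child_rng(seed, "activity-intercepts", phase, net)
        intercepts = {
            s: icp_rng.normal(0.0, c.study_intercept_sd) for s in study_ids
        }
        noise_rng = child_rng(seed, "activity-noise", phase, net)
        unknown = set(tdf["study_id"]) - set(intercepts)
        if unknown:
            raise KeyError(f"unknown study id(s): {sorted(unknown)}")
        mu = (
            tdf["study_id"].map(intercepts).to_numpy()
            + c.beta_PE * tdf["z_pe"].to_numpy()
            + c.beta_AB * tdf["z_ab"].to_numpy()
            + c.beta_interaction * (tdf["z_pe"] * tdf["z_ab"]).to_numpy()
        )
        y = mu + noise_rng.normal(0.0, c.noise_sd, len(tdf))
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tdf["participant_id"],
                    "study_id": tdf["study_id"],
                    "network": net,
                    "phase": phase,
                    "activity": y,
                }
            )
        )
        truth_rows.append(
            {"network": net, "phase": phase, **c.__dict__}
        )
    activity = pd.concat(frames, ignore_index=True)
    return activity, pd.DataFrame(truth_rows)


def make_event_schedule(
    n_trials: int,
    encoding_duration: float = 2.0,
    delay_duration: float = 9.0,
    response_duration: float = 3.0,
    iti: float = 4.0,
    start: float = 6.0,
) -> pd.DataFrame:
    """A regular encoding/delay/response event schedule (seconds)."""
    rows = []
    t = start
    for k in range(n_trials):
        rows.append(
            {
                "trial": k,
                "encoding_onset": t,
                "encoding_duration": encoding_duration,
                "delay_onset": t + encoding_duration,
                "delay_duration": delay_duration,
                "response_onset": t + encoding_duration + delay_duration,
                "response_duration": response_duration,
                "outlier": False,
            }
        )
        t += encoding_duration + delay_duration + response_duration + iti
    return pd.DataFrame(rows)


def simulate_timeseries(
    schedule: pd.DataFrame,
    truths: Sequence[ParticipantTruth],
    glm_truth: Mapping[str, float],
    seed: int = 0,
    tr: float = 1.0,
    n_frames: int | None = None,
    networks: Sequence[str] = ("network_1",),
    noise_sd: float = 1.0,
    fir_order: int = 8,
):
    """Forward task-GLM model: ``y = X @ beta_true + Normal noise``.

    The design matrix is built by :func:`swmkit.taskglm.build_design_matrix`
    from ``schedule`` (no motion regressors are simulated).  ``glm_truth``
    maps regressor names to true coefficients; unnamed regressors are 0.
    Returns ``(timeseries, design, beta_true_vector)`` where ``timeseries``
    is long-format (participant, network, frame, value).
    """
    from . import taskglm  # local import: synthdata is taskglm's forward model

    if not truths:
        raise ValueError("truths must be non-empty")
    if tr <= 0:
        raise ValueError("TR must be positive")
    if n_frames is None:
        end = (schedule["response_onset"] + schedule["response_duration"]).max()
        n_frames = int(np.ceil((end + 16.0) / tr))
    design = taskglm.build_design_matrix(
        schedule, motion=None, tr=tr, n_frames=n_frames, fir_order=fir_order
    )
    beta_true = np.array([glm_truth.get(name, 0.0) for name in design.names])
    mu = design.matrix @ beta_true

    frames = []
    for t in truths:
        for net in networks:
            rng = child_rng(seed, "timeseries", t.participant_id, net)
            y = mu + rng.normal(0.0, noise_sd, n_frames)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": t.participant_id,
                        "network": net,
                        "frame": np.arange(n_frames),
                        "value": y,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True), design, beta_true
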