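"""Bootstrap analysis of sample-size effects on brain-behavior estimates.

For each sample size n on a grid, participants are resampled with
replacement B times; the random-intercept-by-study model is refit on every
resample and the distribution of standardized betas, effect sizes and
FDR-corrected significance is aggregated into a curve: the empirical
spread of beta shrinks with n, small-sample effect sizes are inflated, and
statistical power — the proportion of resamples whose FDR-corrected effect
is significant — grows with n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .brainbehavior import LMMSpec, cohens_f2, fdr_bh, fit_random_intercept_lmm

logger = logging.getLogger(__name__)

__all__ = ["ResamplingCurve", "prepare_bootstrap_data", "bootstrap_curve",
           "stabilization_n"]


@dataclass
class ResamplingCurve:
    """Aggregated bootstrap results per (n, network, term)."""

    table: pd.DataFrame
    n_grid: tuple[int, ...]
    B: int
    alpha: float
    seed: int
    n_failed: int = 0


def prepare_bootstrap_data(
    data: pd.DataFrame,
    networks: tuple[str, ...],
    phase: str = "delay",
) -> pd.DataFrame:
    """Pivot a standardized long activity table to one row per participant.

    ``data`` is the output of
    :func:`swmkit.brainbehavior.standardize_activity`; the result has the
    behavioral z-scores plus one ``activity:<network>`` column each, so a
    participant resample carries all their measurements together.
    """
    sub = data[data["phase"] == phase]
    wide = sub.pivot_table(
        index=["participant_id", "study_id",
               "z_pure_angular_error", "z_angular_bias"],
        columns="network",
        values="activity",
    ).reset_index()
    missing = [n for n in networks if n not in wide.columns]
    if missing:
        raise ValueError(f"networks absent from activity table: {missing}")
    return wide.rename(columns={n: f"activity:{n}" for n in networks})


def bootstrap_curve(
    data: pd.DataFrame,
    networks: tuple[str, ...],
    n_grid: tuple[int, ...],
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    spec: LMMSpec = LMMSpec(engine="fast"),
    compute_f2: bool = True,
    max_redraws: int = 100,
) -> ResamplingCurve:
    """Participant-level bootstrap of the brain-behavior model.

    ``data`` is the wide per-participant table from
    :func:`prepare_bootstrap_data`.  Each resample draws n participants with
    replacement (redrawn until it spans >= 2 studies; a resample that fails
    ``max_redraws`` times is recorded as failed and skipped).  FDR is
    applied across ``networks`` within each resample, separately per model
    term; non-convergent fits count as non-significant.
    """
    rows = []
    n_failed = 0
    terms = spec.terms()
    idx_all = np.arange(len(data))
    studies = data["study_id"].to_numpy()
    for n in n_grid:
        rng = child_rng(seed, "bootstrap", int(n))
        betas = {(net, t): [] for net in networks for t in terms}
        f2s = {(net, t): [] for net in networks for t in terms}
        sig = {(net, t): [] for net in networks for t in terms}
        for b in range(B):
            for _ in range(max_redraws):
                take = rng.choice(idx_all, size=n, replace=True)
                if len(np.unique(studies[take])) >= 2:
                    break
            else:
                n_failed += 1
                logger.warning("n=%d resample %d: single study after %d redraws",
                               n, b, max_redraws)
                continue
            sample = data.iloc[take]
            pvals = {t: [] for t in terms}
            fit_ok = {}
            fits = {}
            for net in networks:
                cell = sample.rename(columns={f"activity:{net}": "activity"})
                try:
                    res = fit_random_intercept_lmm(cell, spec)
                except ValueError:
                    res = None
                fits[net] = (cell, res)
                fit_ok[net] = res is not None and res.converged
                for t in terms:
                    pvals[t].append(
                        res.terms.set_index("term").loc[t, "p"]
                        if res is not None else 1.0
                    )
            for t in terms:
                _, rej = fdr_bh(np.asarray(pvals[t]), alpha=alpha)
                for j, net in enumerate(networks):
                    cell, res = fits[net]
                    if res is None:
                        continue
                    betas[(net, t)].append(res.beta(t))
                    sig[(net, t)].append(bool(rej[j]) and fit_ok[net])
                    if compute_f2 and ":" not in t:
                        f2s[(net, t)].append(cohens_f2(cell, spec, t, full=res))
        for net in networks:
            for t in terms:
                bvals = np.asarray(betas[(net, t)])
                if bvals.size == 0:
                    continue
                qs = np.percentile(bvals, [0.5, 2.5, 97.5, 99.5])
                rows.append(
                    {
                        "n": n,
                        "network": net,
                        "term": t,
                        "mean_beta": bvals.mean(),
                        "min_beta": bvals.min(),
                        "max_beta": bvals.max(),
                        "lo99": qs[0], "lo95": qs[1],
                        "hi95": qs[2], "hi99": qs[3],
                        "mean_f2": (np.mean(f2s[(net, t)])
                                    if f2s[(net, t)] else np.nan),
                        "power": float(np.mean(sig[(net, t)])),
                        "n_resamples": int(bvals.size),
                    }
                )
    table = pd.DataFrame(rows).sort_values(["network", "term", "n"]).reset_index(
        drop=True
    )
    return ResamplingCurve(table, tuple(int(v) for v in n_grid), B, alpha,
                           seed, n_failed)


def stabilization_n(curve: ResamplingCurve) -> pd.DataFrame:
    """Smallest n from which the central 95% beta interval excludes zero.

    Per (network, term): the smallest grid n such that the interval
    excludes 0 there and at every larger grid point; NaN when never
    sustained ("not reached").
    """
    rows = []
    for (net, term), grp in curve.table.groupby(["network", "term"]):
        grp = grp.sort_values("n")
        excl = ((grp["lo95"] > 0) | (grp["hi95"] < 0)).to_numpy()
        ns = grp["n"].to_numpy()
        stab = np.nan
        for i in range(len(ns)):
            if excl[i:].all():
                stab = int(ns[i])
                break
        rows.append({"network": net, "term": term, "n_stabilize": stab})
    return pd.DataFrame(rows)
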