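"""Frequentist brain-behavior modeling across pooled studies.

Network activity (standardized within study) is regressed on the
standardized behavioral measures — pure angular error and angular bias,
plus their interaction by default — with a random intercept per study to
absorb systematic between-study differences.  Reported coefficients are
standardized betas with Wald (normal-approximation) two-tailed p-values,
Cohen's f-squared effect sizes from marginal (fixed-effects) R-squared, and
Benjamini-Hochberg FDR across the networks of interest within each phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMMSpec",
    "LMMResult",
    "fit_random_intercept_lmm",
    "marginal_r2",
    "cohens_f2",
    "fdr_bh",
    "standardize_activity",
    "run_phase_analysis",
    "DEFAULT_FAMILY",
]

#: FDR family: the four networks of interest within each phase.
DEFAULT_FAMILY = (
    "cingulo-opercular",
    "dorsal-attention",
    "frontoparietal",
    "default",
)


@dataclass(frozen=True)
class LMMSpec:
    """Model specification for the random-intercept-by-study linear model."""

    response: str = "activity"
    fixed: tuple[str, ...] = ("z_pure_angular_error", "z_angular_bias")
    interaction: bool = True
    group: str = "study_id"
    reml: bool = True
    #: terms excluded from the design (used to build nested reduced models)
    drop: tuple[str, ...] = ()
    #: "statsmodels" (MixedLM) or "fast" (profiled-REML scalar solver); the
    #: two fit the identical model and are cross-checked in the test suite
    engine: str = "statsmodels"

    def terms(self) -> list[str]:
        t = list(self.fixed)
        if self.interaction and len(self.fixed) >= 2:
            t.append(f"{self.fixed[0]}:{self.fixed[1]}")
        return [x for x in t if x not in self.drop]


@dataclass
class LMMResult:
    """Fitted fixed effects plus variance components of one model."""

    terms: pd.DataFrame          # term, beta, se, stat, p
    group_var: float
    resid_var: float
    n: int
    converged: bool
    marginal_r2: float

    def beta(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "beta"])


def _design(data: pd.DataFrame, spec: LMMSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for t in spec.terms():
        if ":" in t:
            a, b = t.split(":")
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
        else:
            cols.append(data[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


def marginal_r2(X: np.ndarray, beta: np.ndarray, group_var: float,
                resid_var: float) -> float:
    """Proportion of variance explained by the fixed effects.

    ``var(X beta) / (var(X beta) + group_var + resid_var)`` — the marginal
    R-squared of a mixed model; reduces to the usual R-squared for an
    ordinary regression (group variance 0).
    """
    var_f = float(np.var(X @ beta))
    denom = var_f + group_var + resid_var
    return var_f / denom if denom > 0 else 0.0


def fit_random_intercept_lmm(data: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    """Fit the random-intercept model; never raises on non-convergence.

    With a single study (or a degenerate random-effect variance) the model
    collapses to ordinary least squares with the group variance pinned at
    zero.  Wald two-tailed p-values use the normal approximation.
    """
    if data[list(spec.fixed) + [spec.response, spec.group]].isna().any().any():
        raise ValueError("missing values in model variables")
    if len(data) < 10:
        raise ValueError("need >= 10 observations")
    y = data[spec.response].to_numpy(float)
    X, names = _design(data, spec)
    groups = data[spec.group].to_numpy()
    n_groups = len(np.unique(groups))

    if np.var(y) == 0:
        terms = pd.DataFrame(
            {"term": names, "beta": 0.0, "se": 0.0, "stat": 0.0, "p": 1.0}
        )
        terms.loc[terms["term"] == "intercept", "beta"] = y.mean()
        return LMMResult(terms, 0.0, 0.0, len(y), True, 0.0)

    if n_groups < 2:
        return _ols_result(y, X, names)

    if spec.engine == "fast":
        return _fast_lmm(y, X, names, groups, reml=spec.reml)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            fit = MixedLM(y, X, groups=groups).fit(reml=spec.reml)
            converged = bool(fit.converged)
        except (np.linalg.LinAlgError, ValueError):
            res = _ols_result(y, X, names)
            return replace(res, converged=False)
        group_var = float(np.asarray(fit.cov_re).squeeze())
        beta = np.asarray(fit.fe_params)
        with np.errstate(invalid="ignore"):
            se = np.asarray(fit.bse_fe)
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)) \
            or np.any(se > 1e3):
        # degenerate boundary fit (e.g. zero between-study variance can
        # produce unusable Wald SEs); the profiled solver handles it exactly
        return _fast_lmm(y, X, names, groups, reml=spec.reml)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * _st.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"term": names, "beta": beta, "se": se, "stat": z, "p": p}
    )
    return LMMResult(
        terms,
        group_var=max(group_var, 0.0),
        resid_var=float(fit.scale),
        n=len(y),
        converged=converged,
        marginal_r2=marginal_r2(X, beta, max(group_var, 0.0), float(fit.scale)),
    )


def _fast_lmm(y: np.ndarray, X: np.ndarray, names: list[str],
              groups: np.ndarray, reml: bool = True) -> LMMResult:
    """Profiled (RE)ML for the one-way random-intercept model.

    With a single variance ratio ``lam = tau^2 / sigma^2`` the GLS weights
    have the closed form ``V_s^-1 proportional to I - lam/(1 + lam n_s) 11'``
    per group, so beta and sigma^2 concentrate out and the criterion is
    optimized over ``log lam`` by scalar bounded search.  Identical model to
    the MixedLM engine, orders of magnitude faster for small p.
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    labels, idx = np.unique(groups, return_inverse=True)
    S = labels.size
    n_s = np.bincount(idx).astype(float)
    # per-group sufficient statistics
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Gx = np.zeros((S, p))
    Gy = np.zeros(S)
    for j in range(p):
        Gx[:, j] = np.bincount(idx, weights=X[:, j], minlength=S)
    Gy = np.bincount(idx, weights=y, minlength=S)

    def _moments(lam: float):
        c = lam / (1.0 + lam * n_s)
        A = XtX - (Gx * c[:, None]).T @ Gx
        b = Xty - Gx.T @ (c * Gy)
        q = yty - float(c @ Gy**2)
        return A, b, q, c

    def neg_crit(loglam: float) -> float:
        lam = np.exp(loglam)
        A, b, q, _ = _moments(lam)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        rwr = max(q - b @ beta, 1e-300)
        logdet_v = float(np.sum(np.log1p(lam * n_s)))
        if reml:
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return 0.5 * ((n - p) * np.log(rwr) + logdet_v + logdet_a)
        return 0.5 * (n * np.log(rwr) + logdet_v)

    res = minimize_scalar(neg_crit, bounds=(-14.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    if neg_crit(-30.0) <= res.fun:  # boundary: no between-study variance
        lam = 0.0
    A, b, q, _ = _moments(lam)
    beta = np.linalg.solve(A, b)
    rwr = max(q - b @ beta, 0.0)
    sigma2 = rwr / (n - p) if reml else rwr / n
    group_var = lam * sigma2
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * _st.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"term": names, "beta": beta, "se": se, "stat": z, "p": pvals}
    )
    return LMMResult(
        terms, group_var=group_var, resid_var=float(sigma2), n=n,
        converged=True,
        marginal_r2=marginal_r2(X, beta, group_var, float(sigma2)),
    )


def _ols_result(y: np.ndarray, X: np.ndarray, names: list[str]) -> LMMResult:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - rank, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * _st.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"term": names, "beta": beta, "se": se, "stat": z, "p": p}
    )
    return LMMResult(terms, 0.0, s2, len(y), True, marginal_r2(X, beta, 0.0, s2))


def cohens_f2(data: pd.DataFrame, spec: LMMSpec, term: str,
              full: LMMResult | None = None) -> float:
    """Cohen's f-squared for one fixed effect.

    ``f2 = (R2_full - R2_reduced) / (1 - R2_full)`` with R-squared the
    marginal (fixed-effects) proportion of explained variance; the reduced
    model drops only the focal term.
    """
    if full is None:
        full = fit_random_intercept_lmm(data, spec)
    if term not in spec.terms():
        raise ValueError(f"term '{term}' not in model")
    reduced = fit_random_intercept_lmm(
        data, replace(spec, drop=spec.drop + (term,))
    )
    r2f, r2r = full.marginal_r2, reduced.marginal_r2
    if r2f >= 1.0:
        raise ValueError("full-model R2 >= 1; f2 undefined")
    return max((r2f - r2r) / (1.0 - r2f), 0.0)


def fdr_bh(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns ``(q, reject)`` in the input order: ``q_i = min_{j >= rank(i)}
    m * p_(j) / j`` capped at 1, rejection iff ``q <= alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def standardize_activity(
    activity: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Join activity with behavioral summaries and z-score it within study.

    Excluded participants are dropped; standardization is per
    (phase, network) over the retained participants of each study.
    """
    for col in ("participant_id", "network", "phase", "activity"):
        if col not in activity.columns:
            raise ValueError(f"activity table missing column '{col}'")
    keep = summaries[~summaries["excluded"]]
    merged = activity.merge(
        keep[["participant_id", "study_id",
              "z_pure_angular_error", "z_angular_bias"]],
        on="participant_id",
        how="inner",
        suffixes=("", "_summary"),
    )
    if merged.empty:
        raise ValueError("no joinable participants between activity and summaries")
    if "study_id_summary" in merged.columns:
        merged["study_id"] = merged.pop("study_id_summary")

    def z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("constant activity within a study cell")
        return (x - x.mean()) / sd

    merged["activity"] = merged.groupby(
        ["phase", "network", "study_id"], group_keys=False
    )["activity"].apply(z)
    return merged


def run_phase_analysis(
    activity: pd.DataFrame,
    summaries: pd.DataFrame,
    networks: tuple[str, ...] | None = None,
    phases: tuple[str, ...] | None = None,
    spec: LMMSpec = LMMSpec(),
    alpha: float = 0.05,
    compute_f2: bool = True,
) -> pd.DataFrame:
    """One random-intercept model per (network, phase), FDR across networks.

    Returns a tidy table (phase, network, term, beta, se, p, f2, q, reject,
    converged) sorted by phase/network; the BH family is the networks of
    interest within each phase, applied separately per model term.  f2 is
    reported for the main effects.
    """
    data = standardize_activity(activity, summaries)
    if networks is None:
        networks = tuple(
            n for n in DEFAULT_FAMILY if n in set(data["network"])
        ) or tuple(sorted(data["network"].unique()))
    if phases is None:
        phases = tuple(sorted(data["phase"].unique()))

    rows = []
    for phase in phases:
        for net in networks:
            cell = data[(data["phase"] == phase) & (data["network"] == net)]
            res = fit_random_intercept_lmm(cell, spec)
            for term in spec.terms():
                f2 = (
                    cohens_f2(cell, spec, term, full=res)
                    if compute_f2 and ":" not in term
                    else np.nan
                )
                trow = res.terms.set_index("term").loc[term]
                rows.append(
                    {
                        "phase": phase,
                        "network": net,
                        "term": term,
                        "beta": trow["beta"],
                        "se": trow["se"],
                        "p": trow["p"],
                        "f2": f2,
                        "converged": res.converged,
                    }
                )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["reject"] = False
    for (phase, term), idx in out.groupby(["phase", "term"]).groups.items():
        q, rej = fdr_bh(out.loc[idx, "p"].to_numpy(), alpha=alpha)
        out.loc[idx, "q"] = q
        out.loc[idx, "reject"] = rej
    return out.sort_values(["phase", "network", "term"]).reset_index(drop=True)
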