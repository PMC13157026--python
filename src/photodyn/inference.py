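"""Trend inference for clustered response metrics.

Pooled OLS of a response measure on stimulus intensity with subject-level
cluster-robust standard errors (CR1 small-sample factor), a studentized wild
cluster bootstrap-t p-value (two-point Mammen weights, plus-one correction,
two-sided, null imposed by default) and confidence intervals obtained by
inverting the bootstrap test with common random numbers. Also provides
per-subject slopes, the classical paired t-test and Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendFit",
    "PairedTestResult",
    "DegenerateDifferencesError",
    "fit_cluster_ols",
    "per_subject_slopes",
    "mammen_weights",
    "rademacher_weights",
    "wild_cluster_boot_p",
    "wild_cluster_trend",
    "invert_ci",
    "ci_contains",
    "paired_t",
    "bonferroni_adjust",
    "MAMMEN_LOW",
    "MAMMEN_HIGH",
    "MAMMEN_P_LOW",
]

# Two-point law with E w = 0, E w^2 = 1, E w^3 = 1
_SQRT5 = math.sqrt(5.0)
MAMMEN_LOW = (1.0 - _SQRT5) / 2.0
MAMMEN_HIGH = (1.0 + _SQRT5) / 2.0
MAMMEN_P_LOW = (1.0 + _SQRT5) / (2.0 * _SQRT5)


class DegenerateDifferencesError(ValueError):
    """Raised when paired differences have zero variance."""


@dataclass(frozen=True)
class TrendFit:
    beta: float
    intercept: float
    cr_se: float
    t_stat: float
    n_clusters: int
    n_obs: int
    degenerate: bool = False
    p_boot: float | None = None
    ci: tuple[float, float] | None = None
    B: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d = dict(
            beta=self.beta,
            intercept=self.intercept,
            cr_se=self.cr_se,
            t=self.t_stat,
            p=self.p_boot,
            ci_lo=None if self.ci is None else self.ci[0],
            ci_hi=None if self.ci is None else self.ci[1],
            B=self.B,
            seed=self.seed,
            n_clusters=self.n_clusters,
            n_obs=self.n_obs,
            degenerate=self.degenerate,
        )
        return d


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    p_adjusted: float
    m: int


# ---------------------------------------------------------------------------
# Design helpers
# ---------------------------------------------------------------------------

def _design(data: pd.DataFrame):
    """Extract (y, X, cluster row-index lists) from a long table."""
    y = np.asarray(data["value"], dtype=float)
    x = np.asarray(data["intensity"], dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    codes, _ = pd.factorize(data["subject_id"], sort=True)
    groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    return y, X, groups


def _cr1_factor(n_clusters: int, n_obs: int, k: int = 2) -> float:
    return (n_clusters / (n_clusters - 1.0)) * ((n_obs - 1.0) / (n_obs - k))


def _ols_with_cluster_se(y: np.ndarray, X: np.ndarray, groups) -> tuple[np.ndarray, float, bool]:
    """Return (coef, cluster-robust SE of the slope, degenerate flag)."""
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (all intensities equal?)")
    A = np.linalg.inv(xtx)
    coef = A @ (X.T @ y)
    u = y - X @ coef
    meat = np.zeros((2, 2))
    for idx in groups:
        s = X[idx].T @ u[idx]
        meat += np.outer(s, s)
    c = _cr1_factor(len(groups), y.size)
    V = c * (A @ meat @ A)
    var = V[1, 1]
    degenerate = bool(np.allclose(u, 0.0, atol=1e-10 * max(1.0, np.abs(y).max())))
    if degenerate:
        return coef, 0.0, True
    return coef, math.sqrt(max(var, 0.0)), degenerate


def fit_cluster_ols(data: pd.DataFrame) -> TrendFit:
    """Pooled OLS of value on intensity with CR1 cluster-robust slope SE.

    ``data`` is a long table with columns subject_id, intensity, value;
    clusters are subjects. Requires at least two clusters.
    """
    y, X, groups = _design(data)
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters (subjects)")
    coef, se, degenerate = _ols_with_cluster_se(y, X, groups)
    t_stat = float("inf") if se == 0 else coef[1] / se
    if degenerate:
        t_stat = float("inf") if coef[1] != 0 else 0.0
    return TrendFit(
        beta=float(coef[1]),
        intercept=float(coef[0]),
        cr_se=float(se),
        t_stat=float(t_stat),
        n_clusters=len(groups),
        n_obs=int(y.size),
        degenerate=degenerate,
    )


def per_subject_slopes(data: pd.DataFrame) -> pd.DataFrame:
    """Independent simple OLS per subject.

    Subjects with fewer than two distinct intensities are skipped; they are
    listed in the frame's ``attrs['skipped']``.
    """
    rows, skipped = [], []
    for sid, grp in data.groupby("subject_id", sort=True):
        x = np.asarray(grp["intensity"], dtype=float)
        y = np.asarray(grp["value"], dtype=float)
        if np.unique(x).size < 2:
            skipped.append(sid)
            continue
        beta, intercept = np.polyfit(x, y, 1)
        rows.append(dict(subject_id=sid, beta=float(beta), intercept=float(intercept)))
    out = pd.DataFrame(rows, columns=["subject_id", "beta", "intercept"])
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Wild cluster bootstrap
# ---------------------------------------------------------------------------

def mammen_weights(n_clusters: int, seed=0, size: int | None = None) -> np.ndarray:
    """Draw Mammen two-point weights, one per cluster.

    w = (1-sqrt(5))/2 with probability (1+sqrt(5))/(2 sqrt(5)), else
    (1+sqrt(5))/2, i.i.d. With ``size`` given, returns a (size, n_clusters)
    matrix.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n_clusters,) if size is None else (size, n_clusters)
    return np.where(rng.random(shape) < MAMMEN_P_LOW, MAMMEN_LOW, MAMMEN_HIGH)


def rademacher_weights(n_clusters: int, seed=0, size: int | None = None) -> np.ndarray:
    """+/-1 weights with equal probability (alternative weight-law stub)."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n_clusters,) if size is None else (size, n_clusters)
    return np.where(rng.random(shape) < 0.5, -1.0, 1.0)


def _boot_t_stats(
    y: np.ndarray,
    X: np.ndarray,
    groups,
    W: np.ndarray,
    beta0: float,
    impose_null: bool,
) -> tuple[float, np.ndarray]:
    """Observed t and bootstrap t* for H0: slope = beta0.

    Vectorised over the B rows of the weight matrix ``W``; replicates with a
    degenerate (zero) bootstrap SE get t* = +inf so they count as
    exceedances (conservative).
    """
    G = len(groups)
    N = y.size
    A = np.linalg.inv(X.T @ X)
    coef = A @ (X.T @ y)
    _, se_obs, _ = _ols_with_cluster_se(y, X, groups)
    if se_obs == 0:
        t_obs = 0.0 if coef[1] == beta0 else math.inf
    else:
        t_obs = (coef[1] - beta0) / se_obs

    if impose_null:
        ytilde = y - beta0 * X[:, 1]
        alpha = ytilde.mean()
        f = alpha + beta0 * X[:, 1]
        center = beta0
    else:
        f = X @ coef
        center = coef[1]
    u = y - f

    # per-cluster building blocks
    h = np.stack([X[idx].T @ f[idx] for idx in groups])  # G x 2
    s = np.stack([X[idx].T @ u[idx] for idx in groups])  # G x 2
    M = np.stack([X[idx].T @ X[idx] for idx in groups])  # G x 2 x 2

    H = h.sum(axis=0)  # (2,)
    # coefficients for all replicates: 2 x B
    coef_all = A @ (H[:, None] + s.T @ W.T)

    a1 = A[1]  # row of A picking the slope component
    p_g = h @ a1  # (G,)
    q_g = s @ a1  # (G,)
    R = np.einsum("gij,i->gj", M, a1)  # G x 2

    # slope component of each cluster score, per replicate: G x B
    V = p_g[:, None] + q_g[:, None] * W.T - R @ coef_all
    c = _cr1_factor(G, N)
    var = c * np.sum(V * V, axis=0)
    beta_star = coef_all[1]

    t_star = np.full(W.shape[0], math.inf)
    ok = var > 0
    t_star[ok] = (beta_star[ok] - center) / np.sqrt(var[ok])
    return t_obs, t_star


def _boot_pvalue(y, X, groups, W, beta0: float, impose_null: bool) -> float:
    """Plus-one bootstrap p conditioned on informative weight draws.

    A draw that gives every cluster the same weight rescales the data
    exactly, so its |t*| equals |t_obs| by construction and carries no
    information about the null (with Mammen weights and few clusters such
    draws are common: probability 0.7236^G + 0.2764^G). They are excluded
    from both the exceedance count and the denominator; replicates with a
    degenerate bootstrap SE still count as exceedances (t* = inf).
    """
    t_obs, t_star = _boot_t_stats(y, X, groups, W, beta0, impose_null)
    informative = ~np.all(W == W[:, :1], axis=1)
    exceed = np.count_nonzero(informative & (np.abs(t_star) >= abs(t_obs)))
    return (1.0 + exceed) / (np.count_nonzero(informative) + 1.0)


def wild_cluster_boot_p(
    data: pd.DataFrame,
    beta0: float = 0.0,
    B: int = 999,
    seed=0,
    impose_null: bool = True,
    weights: np.ndarray | None = None,
) -> float:
    """Studentized wild cluster bootstrap-t p-value for H0: slope = beta0.

    Two-sided via |t|, with the plus-one correction
    p = (1 + #{b : |t*_b| >= |t_obs|}) / (B + 1). ``weights`` may supply a
    pre-drawn (B x G) Mammen weight matrix (used for test inversion with
    common random numbers).
    """
    y, X, groups = _design(data)
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters (subjects)")
    W = mammen_weights(len(groups), seed, size=B) if weights is None else weights
    return _boot_pvalue(y, X, groups, W, beta0, impose_null)


def invert_ci(
    data: pd.DataFrame,
    level: float = 0.95,
    B: int = 999,
    seed=0,
    impose_null: bool = True,
    max_expand: int = 60,
    max_bisect: int = 200,
) -> tuple[float, float]:
    """Test-inversion confidence interval {beta0 : p(beta0) >= 1 - level}.

    A single (B x G) Mammen weight matrix is drawn once and reused for every
    beta0 (common random numbers), which makes p(beta0) monotone on each
    side of the estimate so bisection is well defined. Endpoint tolerance is
    1e-3 * cr_se.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    y, X, groups = _design(data)
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters (subjects)")
    fit = fit_cluster_ols(data)
    if fit.cr_se == 0:
        return (fit.beta, fit.beta)
    alpha = 1.0 - level
    W = mammen_weights(len(groups), seed, size=B)

    def p_at(b0: float) -> float:
        return _boot_pvalue(y, X, groups, W, b0, impose_null)

    tol = 1e-3 * fit.cr_se

    def endpoint(direction: float) -> float:
        inside = fit.beta
        step = 2.0 * fit.cr_se
        outside = None
        for _ in range(max_expand):
            cand = fit.beta + direction * step
            if p_at(cand) < alpha:
                outside = cand
                break
            inside = cand
            step *= 2.0
        if outside is None:
            raise RuntimeError(
                f"test inversion did not reject within the search bracket "
                f"(direction {direction:+.0f}, last beta0 {inside})"
            )
        for _ in range(max_bisect):
            if abs(outside - inside) <= tol:
                break
            mid = 0.5 * (inside + outside)
            if p_at(mid) >= alpha:
                inside = mid
            else:
                outside = mid
        return 0.5 * (inside + outside)

    return (endpoint(-1.0), endpoint(+1.0))


def ci_contains(
    data: pd.DataFrame,
    beta0: float,
    level: float = 0.95,
    B: int = 999,
    seed=0,
    impose_null: bool = True,
) -> bool:
    """Membership test for the inversion CI: p(beta0) >= 1 - level with the
    same common-random-number weights ``invert_ci`` would use."""
    y, X, groups = _design(data)
    W = mammen_weights(len(groups), seed, size=B)
    return bool(_boot_pvalue(y, X, groups, W, beta0, impose_null) >= 1.0 - level)


def wild_cluster_trend(
    data: pd.DataFrame,
    B: int = 10000,
    seed=0,
    level: float = 0.95,
    beta0: float = 0.0,
    impose_null: bool = True,
) -> TrendFit:
    """Full trend analysis: fit, bootstrap p and test-inversion CI."""
    fit = fit_cluster_ols(data)
    p = wild_cluster_boot_p(data, beta0=beta0, B=B, seed=seed, impose_null=impose_null)
    if fit.cr_se == 0:
        ci = (fit.beta, fit.beta)
    else:
        ci = invert_ci(data, level=level, B=B, seed=seed, impose_null=impose_null)
    return replace(fit, p_boot=p, ci=ci, B=B, seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------

def paired_t(x, y) -> PairedTestResult:
    """Classical paired t-test on x - y, two-sided p from t with df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDifferencesError("paired differences have zero variance")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p), p_adjusted=float(p), m=1)


def bonferroni_adjust(p_values) -> np.ndarray:
    """p_adj = min(1, m * p) with m = number of comparisons."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)
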