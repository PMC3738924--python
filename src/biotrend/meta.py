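"""Inverse-variance meta-analysis of per-cell change estimates.

Cells at one spatial scale are combined into a weighted mean logratio (Qw)
under a random-effects model, y_i ~ N(mu, v_i + tau2), with tau2 by REML
(DerSimonian-Laird available). Residual sampling-effort bias is probed by a
weighted meta-regression on the effort moderator delta_r; when the moderator
is significant, per-cell partial residuals remove its fitted effect before
per-cell z-tests. Spatial structure in the adjusted values is assessed by
profiling GLS models with exponential or linear correlation against an
independent-errors null (likelihood-ratio test and AIC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetaResult",
    "ModeratorFit",
    "random_effects_meta",
    "moderator_regression",
    "partial_residuals",
    "cell_z_tests",
    "SpatialAutocorrResult",
    "spatial_autocorr_test",
    "analyze_scale",
    "ScaleAnalysis",
]


# ---------------------------------------------------------------------------
# tau2 estimation


def _dl_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator (intercept-only)."""
    w = 1.0 / v
    ybar = (w * y).sum() / w.sum()
    q = (w * (y - ybar) ** 2).sum()
    df = len(y) - X.shape[1]
    c = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (q - df) / c)


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    xtw = X.T * w
    xtwx = xtw @ X
    beta = np.linalg.solve(xtwx, xtw @ y)
    cov = np.linalg.inv(xtwx)
    resid = y - X @ beta
    return beta, cov, resid


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    beta, cov, resid = _wls(y, X, w)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return 0.5 * (np.log(v + tau2).sum() + logdet + (w * resid**2).sum())


def _reml_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    upper = max(10.0 * float(np.var(y)), 10.0 * float(v.max()), 1e-3)
    res = optimize.minimize_scalar(
        _reml_nll, bounds=(0.0, upper), args=(y, v, X), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # the bounded optimiser never lands exactly on 0; check the boundary
    if _reml_nll(0.0, y, v, X) <= _reml_nll(tau2, y, v, X):
        return 0.0
    return tau2


def _estimate_tau2(y, v, X, method: str) -> float:
    if method == "reml":
        return _reml_tau2(y, v, X)
    if method == "dl":
        return _dl_tau2(y, v, X)
    raise ValueError(f"unknown tau2 method {method!r} (use 'reml' or 'dl')")


# ---------------------------------------------------------------------------
# random-effects mean and meta-regression


@dataclass
class MetaResult:
    """Weighted mean change at one scale.

    ``se`` is the classical inverse-variance standard error sqrt(1/sum w);
    ``se_kh`` is the Knapp-Hartung estimator used (with t quantiles on k-1
    df) for the confidence interval and test, which keeps coverage honest
    when the per-cell variances are themselves noisy estimates.
    """

    qw: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    z: float
    p: float
    k: int
    q_stat: float
    q_df: int
    method: str
    se_kh: float = float("nan")
    single_estimate: bool = False

    @property
    def pct_change(self) -> float:
        return (math.exp(self.qw) - 1.0) * 100.0

    @property
    def pct_ci(self) -> tuple[float, float]:
        return ((math.exp(self.ci_low) - 1.0) * 100.0, (math.exp(self.ci_high) - 1.0) * 100.0)


def random_effects_meta(y, v, method: str = "reml") -> MetaResult:
    """Inverse-variance weighted mean with between-cell heterogeneity.

    Weights are 1/(v_i + tau2); the heterogeneity statistic Q and its df are
    reported from the fixed-effect fit. A single estimate passes through
    with its own variance, flagged ``single_estimate``.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if len(y) != len(v):
        raise ValueError("y and v must have equal length")
    if (v <= 0).any():
        raise ValueError("all sampling variances must be > 0")
    if len(y) == 1:
        se = math.sqrt(v[0])
        z = y[0] / se
        p = 2 * stats.norm.sf(abs(z))
        return MetaResult(
            float(y[0]), se, y[0] - 1.96 * se, y[0] + 1.96 * se,
            0.0, z, p, 1, 0.0, 0, method, single_estimate=True,
        )
    k = len(y)
    X = np.ones((k, 1))
    tau2 = _estimate_tau2(y, v, X, method)
    w = 1.0 / (v + tau2)
    qw = float((w * y).sum() / w.sum())
    se = float(math.sqrt(1.0 / w.sum()))
    wf = 1.0 / v
    ybar_f = (wf * y).sum() / wf.sum()
    q_stat = float((wf * (y - ybar_f) ** 2).sum())
    # Knapp-Hartung: scale the variance by the weighted residual mean square
    # and use t quantiles; never let it fall below the classical Wald se
    se_kh = float(
        math.sqrt(max((w * (y - qw) ** 2).sum() / ((k - 1) * w.sum()), 1.0 / w.sum()))
    )
    tc = stats.t.ppf(0.975, df=k - 1)
    z = qw / se_kh
    p = float(2 * stats.t.sf(abs(z), df=k - 1))
    return MetaResult(
        qw, se, qw - tc * se_kh, qw + tc * se_kh, tau2, z, p, k,
        q_stat, k - 1, method, se_kh=se_kh,
    )


@dataclass
class ModeratorFit:
    """Weighted meta-regression of logratio on the effort moderator."""

    intercept: float
    beta: float
    se_intercept: float
    se_beta: float
    p_beta: float
    ci_beta: tuple[float, float]
    tau2: float
    k: int
    method: str
    estimable: bool = True


def moderator_regression(y, v, delta_r, method: str = "reml") -> ModeratorFit:
    """Mixed-effects meta-regression y_i = b0 + b1 * delta_r_i + u_i + e_i.

    Probes whether accumulation-curve standardisation left residual
    effort bias. A constant moderator makes the slope inestimable; callers
    should then fall back to :func:`random_effects_meta`.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    x = np.asarray(delta_r, float)
    if len(y) < 3:
        raise ValueError("meta-regression needs at least 3 estimates")
    if np.ptp(x) == 0:
        return ModeratorFit(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            (float("nan"), float("nan")), float("nan"), len(y), method, estimable=False,
        )
    X = np.column_stack([np.ones(len(y)), x])
    tau2 = _estimate_tau2(y, v, X, method)
    w = 1.0 / (v + tau2)
    beta, cov, _ = _wls(y, X, w)
    se = np.sqrt(np.diag(cov))
    zb = beta[1] / se[1]
    p = float(2 * stats.norm.sf(abs(zb)))
    zc = stats.norm.ppf(0.975)
    return ModeratorFit(
        float(beta[0]), float(beta[1]), float(se[0]), float(se[1]), p,
        (float(beta[1] - zc * se[1]), float(beta[1] + zc * se[1])),
        tau2, len(y), method,
    )


def partial_residuals(y, delta_r, fit: ModeratorFit) -> np.ndarray:
    """Per-cell logratios with the fitted moderator effect removed.

    adjusted_i = y_i - beta * (delta_r_i - mean(delta_r)); centring keeps the
    mean of the adjustment zero so the overall level is untouched.
    """
    y = np.asarray(y, float)
    x = np.asarray(delta_r, float)
    if not fit.estimable:
        return y.copy()
    return y - fit.beta * (x - x.mean())


def cell_z_tests(adjusted, v) -> pd.DataFrame:
    """Two-sided z-test per cell plus Benjamini-Hochberg q-values."""
    adjusted = np.asarray(adjusted, float)
    v = np.asarray(v, float)
    if (v <= 0).any():
        raise ValueError("variances must be positive")
    z = adjusted / np.sqrt(v)
    p = 2 * stats.norm.sf(np.abs(z))
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"z": z, "p": p, "q": q})


# ---------------------------------------------------------------------------
# spatial autocorrelation of adjusted change values


def _corr_matrix(d: np.ndarray, rho: float, structure: str) -> np.ndarray:
    if structure == "exponential":
        return np.exp(-d / rho)
    if structure == "linear":
        return np.maximum(0.0, 1.0 - d / rho)
    raise ValueError(structure)


def _gls_loglik(y: np.ndarray, R: np.ndarray) -> float:
    """Profile (mu, sigma2 out) ML log-likelihood of intercept-only GLS."""
    n = len(y)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return -np.inf
    one = np.ones(n)
    a = np.linalg.solve(L, y)
    b = np.linalg.solve(L, one)
    mu = (b @ a) / (b @ b)
    r = a - mu * b
    sigma2 = (r @ r) / n
    if sigma2 <= 0:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


@dataclass
class SpatialAutocorrResult:
    """Comparison of independent vs spatially correlated error models."""

    loglik: dict[str, float]
    aic: dict[str, float]
    lrt: dict[str, float]
    lrt_p: dict[str, float]
    rho: dict[str, float]
    best: str = ""
    converged: bool = True

    def __post_init__(self):
        if not self.best:
            self.best = min(self.aic, key=self.aic.get)


def spatial_autocorr_test(
    values, coords, structures: tuple[str, ...] = ("exponential", "linear")
) -> SpatialAutocorrResult:
    """Profile-likelihood GLS test for spatial autocorrelation.

    Fits intercept-only models with (i) independent errors and (ii) each
    requested correlation structure (range parameter rho profiled by ML),
    reporting log-likelihoods, AIC (k = 2 for the null, 3 with rho) and a
    1-df likelihood-ratio test of each spatial model against the null. The
    1-df chi-square is conservative for a range parameter on its boundary.
    """
    y = np.asarray(values, float)
    xy = np.asarray(coords, float)
    if len(y) < 10:
        raise ValueError("need at least 10 cells for the spatial test")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    if (d[~np.eye(len(y), dtype=bool)] == 0).any():
        raise ValueError("duplicate cell centroids: distances must be positive")

    ll_null = _gls_loglik(y, np.eye(len(y)))
    loglik = {"null": ll_null}
    aic = {"null": 2 * 2 - 2 * ll_null}
    lrt: dict[str, float] = {}
    lrt_p: dict[str, float] = {}
    rho_hat: dict[str, float] = {}
    dpos = d[d > 0]
    lo, hi = math.log(dpos.min() / 4), math.log(dpos.max() * 8)
    converged = True
    for structure in structures:
        def nll(log_rho: float) -> float:
            R = _corr_matrix(d, math.exp(log_rho), structure)
            # nudge toward PD; the linear (triangular) structure can be
            # indefinite at some ranges in 2-D
            R[np.diag_indices_from(R)] += 1e-8
            ll = _gls_loglik(y, R)
            return 1e12 if not np.isfinite(ll) else -ll

        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        ll = -float(res.fun)
        if not np.isfinite(ll):
            converged = False
            ll = ll_null
            rho_hat[structure] = float("nan")
        else:
            rho_hat[structure] = math.exp(float(res.x))
        ll = max(ll, ll_null)  # spatial model nests the null in the rho->0 limit
        loglik[structure] = ll
        aic[structure] = 2 * 3 - 2 * ll
        stat = 2.0 * (ll - ll_null)
        lrt[structure] = stat
        lrt_p[structure] = float(stats.chi2.sf(stat, df=1))
    return SpatialAutocorrResult(loglik, aic, lrt, lrt_p, rho_hat, converged=converged)


# ---------------------------------------------------------------------------
# one-call per-scale analysis


@dataclass
class ScaleAnalysis:
    """Meta-analysis of one scale: overall mean, moderator, per-cell table."""

    meta: MetaResult
    moderator: ModeratorFit | None
    adjusted_meta: MetaResult | None
    cells: pd.DataFrame
    spatial: SpatialAutocorrResult | None = None


def analyze_scale(
    estimates: pd.DataFrame,
    alpha: float = 0.05,
    tau2_method: str = "reml",
    coords: np.ndarray | None = None,
) -> ScaleAnalysis:
    """Run the full per-scale analysis on a table of change estimates.

    ``estimates`` needs columns ``logratio``, ``var_logratio``, ``delta_r``.
    The moderator adjustment is applied only when its slope is significant
    at ``alpha``; z-tests always run on the (possibly adjusted) values.
    """
    y = estimates["logratio"].to_numpy(float)
    v = estimates["var_logratio"].to_numpy(float)
    x = estimates["delta_r"].to_numpy(float)
    # a completely sampled cell can bootstrap to SD 0; inverse-variance
    # weighting needs v > 0, so floor at the smallest positive cell variance
    if (v <= 0).any():
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError("all cells have zero sampling variance")
        v = np.where(v <= 0, pos.min(), v)
    meta = random_effects_meta(y, v, method=tau2_method)
    moderator = None
    adjusted_meta = None
    adjusted = y.copy()
    if len(y) >= 3 and np.ptp(x) > 0:
        moderator = moderator_regression(y, v, x, method=tau2_method)
        if moderator.estimable and moderator.p_beta < alpha:
            adjusted = partial_residuals(y, x, moderator)
            adjusted_meta = random_effects_meta(adjusted, v, method=tau2_method)
    ztab = cell_z_tests(adjusted, v)
    cells = estimates.copy().reset_index(drop=True)
    cells["adjusted_logratio"] = adjusted
    cells = pd.concat([cells, ztab], axis=1)
    spatial = None
    if coords is not None and len(y) >= 10:
        try:
            spatial = spatial_autocorr_test(adjusted, coords)
        except ValueError:
            spatial = None
    return ScaleAnalysis(meta, moderator, adjusted_meta, cells, spatial)
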