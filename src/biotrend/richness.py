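"""Accumulation-curve richness estimation and the logratio change statistic.

Two assemblages sampled with unequal effort are compared at a shared
"comparison point": the smaller sample's species accumulation curve is
extrapolated (at most threefold its own effort) and, where the larger sample
exceeds three times the smaller, the larger is rarefied down to that same
point. The change statistic is the natural log of the ratio of the two
comparison-point richness values; its sampling variance comes from a
first-order delta method on bootstrap SDs.

Formulas
--------
Interpolation (analytic rarefaction) of an abundance vector n_i, n = sum n_i:

    E[S(m)] = S_obs - sum_i C(n - n_i, m) / C(n, m)

Unseen species (bias-corrected, singleton/doubleton driven):

    f0 = (n-1)/n * f1^2 / (2 f2)            if f2 > 0
    f0 = (n-1)/n * f1 (f1 - 1) / 2          if f2 = 0

Extrapolation by m* additional records:

    S(n + m*) = S_obs + f0 * [1 - (1 - f1 / (n f0 + f1))^m*]

With no singletons the assemblage is treated as completely sampled
(f0 = 0, the curve is flat beyond n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "rarefy",
    "unseen_species",
    "extrapolate",
    "richness_at",
    "ComparisonPlan",
    "comparison_point",
    "bootstrap_sd",
    "ChangeEstimate",
    "estimate_change",
    "sensitivity_modes",
]


def _clean(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size and not np.all(c == np.floor(c)):
        raise ValueError("abundance vector must be integer record counts")
    c = c.astype(np.int64)
    if (c < 0).any():
        raise ValueError("negative abundances")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty assemblage")
    return c


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(counts, m: int) -> float:
    """Expected species count in a random subsample of ``m`` of ``n`` records.

    Exact analytic interpolation of the accumulation curve, computed in
    log-space to keep the binomial coefficients finite at large n.
    """
    c = _clean(counts)
    n = int(c.sum())
    if not 1 <= m <= n:
        raise ValueError(f"rarefaction needs 1 <= m <= n (m={m}, n={n}); use extrapolate beyond n")
    s_obs = len(c)
    rest = n - c
    keep = rest >= m  # species that can be entirely missed by the subsample
    if not keep.any():
        return float(s_obs)
    miss = np.exp(_log_comb(rest[keep], m) - _log_comb(np.float64(n), m))
    return float(s_obs - miss.sum())


def unseen_species(counts) -> float:
    """Bias-corrected estimate of the number of species not yet recorded.

    Driven entirely by singletons (f1) and doubletons (f2); zero singletons
    mean the assemblage is considered well sampled and f0 = 0.
    """
    c = _clean(counts)
    n = int(c.sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2


def extrapolate(counts, m_star: int) -> float:
    """Expected species count after ``m_star`` additional records.

    Valid up to twice the observed effort beyond n (total effort <= 3n, the
    threefold reliability limit of accumulation-curve extrapolation). The
    curve starts at S_obs and saturates at S_obs + f0.
    """
    c = _clean(counts)
    n = int(c.sum())
    if m_star < 0:
        raise ValueError("m_star must be >= 0")
    if m_star > 2 * n:
        raise ValueError(
            f"extrapolation to {n + m_star} records exceeds the threefold limit 3n = {3 * n}"
        )
    s_obs = len(c)
    f0 = unseen_species(c)
    f1 = int((c == 1).sum())
    if f0 == 0.0 or f1 == 0:
        return float(s_obs)
    base = 1.0 - f1 / (n * f0 + f1)
    return float(s_obs + f0 * (1.0 - base**m_star))


def richness_at(counts, m: int) -> float:
    """Accumulation-curve richness at total effort ``m`` (interpolating,
    observed or extrapolating as m falls below, at, or above n)."""
    c = _clean(counts)
    n = int(c.sum())
    if m <= n:
        return rarefy(c, m)
    return extrapolate(c, m - n)


@dataclass(frozen=True)
class ComparisonPlan:
    """Shared effort at which two periods are compared, and how each gets there."""

    cp: int
    mode_pre: str  # "interpolated" | "observed" | "extrapolated"
    mode_post: str

    @property
    def modes(self) -> tuple[str, str]:
        return (self.mode_pre, self.mode_post)


def comparison_point(n1: int, n2: int) -> ComparisonPlan:
    """Choose the common effort for comparing samples of n1 and n2 records.

    If the larger sample is within threefold of the smaller, the smaller is
    extrapolated up to the larger's effort. Beyond threefold, the smaller is
    extrapolated to exactly 3x its effort and the larger rarefied down to
    that same comparison point.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples need at least one record")
    if n1 == n2:
        return ComparisonPlan(n1, "observed", "observed")
    n_min, n_max = min(n1, n2), max(n1, n2)
    if n_max <= 3 * n_min:
        cp = n_max
        mode_small, mode_large = "extrapolated", "observed"
    else:
        cp = 3 * n_min
        mode_small, mode_large = "extrapolated", "interpolated"
    if n1 < n2:
        return ComparisonPlan(cp, mode_small, mode_large)
    return ComparisonPlan(cp, mode_large, mode_small)


def bootstrap_sd(
    counts,
    m: int,
    B: int = 200,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Bootstrap SD of the accumulation-curve estimate at effort ``m``.

    Resamples n records with replacement from the empirical taxon
    distribution, recomputing the interpolated/extrapolated estimate per
    replicate. Applied to *all* endpoint modes, observed included, so that
    under- or over-recording of singletons and doubletons feeds into the
    variance instead of being taken at face value.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    c = _clean(counts)
    n = int(c.sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = c / n
    reps = rng.multinomial(n, p, size=B)
    est = np.empty(B)
    for b in range(B):
        est[b] = richness_at(reps[b], m)
    return float(est.std(ddof=1))


@dataclass
class ChangeEstimate:
    """Per-cell relative richness change between two periods."""

    x1: float
    x2: float
    q: float
    logratio: float
    var_logratio: float
    n1: int
    n2: int
    delta_r: float
    sd1: float
    sd2: float
    plan: ComparisonPlan
    cell: tuple[int, int] | None = None
    scale: float | None = None
    period_pair: tuple[str, str] | None = None

    @property
    def pct_change(self) -> float:
        """Logratio expressed as percent change, (e^logratio - 1) * 100."""
        return (math.exp(self.logratio) - 1.0) * 100.0


def _estimate_under_plan(
    pre_counts, post_counts, plan: ComparisonPlan, B: int, seed
) -> ChangeEstimate:
    pre = _clean(pre_counts)
    post = _clean(post_counts)
    n1, n2 = int(pre.sum()), int(post.sum())
    x1 = richness_at(pre, plan.cp)
    x2 = richness_at(post, plan.cp)
    if x1 <= 0 or x2 <= 0:
        raise ValueError("comparison-point richness must be positive to form a ratio")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s1, s2 = ss.spawn(2)
    sd1 = bootstrap_sd(pre, plan.cp, B=B, seed=np.random.default_rng(s1))
    sd2 = bootstrap_sd(post, plan.cp, B=B, seed=np.random.default_rng(s2))
    q = x2 / x1
    logratio = math.log(q)
    var = sd1**2 / x1**2 + sd2**2 / x2**2
    delta_r = math.log(n2 / n1)
    return ChangeEstimate(x1, x2, q, logratio, var, n1, n2, delta_r, sd1, sd2, plan)


def estimate_change(
    pre_counts, post_counts, B: int = 200, seed: int | None = None
) -> ChangeEstimate:
    """Comparison-point richness change between a pre- and post-period assemblage.

    Returns the ratio Q = X2/X1 of comparison-point richness values, its
    natural log (the "logratio"), the delta-method sampling variance
    sd1^2/X1^2 + sd2^2/X2^2 from bootstrap SDs, and the effort moderator
    delta_r = ln(n2/n1).
    """
    pre = _clean(pre_counts)
    post = _clean(post_counts)
    plan = comparison_point(int(pre.sum()), int(post.sum()))
    return _estimate_under_plan(pre, post, plan, B, seed)


def sensitivity_modes(
    pre_counts,
    post_counts,
    mode: str = "combined",
    B: int = 200,
    seed: int | None = None,
) -> ChangeEstimate:
    """Richness change under a forced standardisation plan.

    ``combined`` is the default protocol; ``interpolation_only`` rarefies the
    larger sample down to the smaller's effort; ``extrapolation_only``
    extrapolates the smaller up to the larger's effort (only valid within the
    threefold limit).
    """
    pre = _clean(pre_counts)
    post = _clean(post_counts)
    n1, n2 = int(pre.sum()), int(post.sum())
    if mode == "combined":
        plan = comparison_point(n1, n2)
    elif mode == "interpolation_only":
        cp = min(n1, n2)
        plan = ComparisonPlan(
            cp,
            "observed" if n1 == cp else "interpolated",
            "observed" if n2 == cp else "interpolated",
        )
    elif mode == "extrapolation_only":
        n_min, n_max = min(n1, n2), max(n1, n2)
        if n_max > 3 * n_min:
            raise ValueError(
                f"extrapolation-only needs n_max <= 3 n_min (got {n_max} > {3 * n_min})"
            )
        cp = n_max
        plan = ComparisonPlan(
            cp,
            "observed" if n1 == cp else "extrapolated",
            "observed" if n2 == cp else "extrapolated",
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _estimate_under_plan(pre, post, plan, B, seed)
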