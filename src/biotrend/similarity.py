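"""Equal-effort assemblage similarity (1-betasim) and distance decay.

Compositional similarity between grid cells is measured by the replacement
component 1-betasim = a / (a + min(b, c)), which ignores nestedness: a cell
whose species are a subset of another's scores 1. Because a random sample of
records from a heavily sampled cell is enriched in common species, raw
similarity is biased by effort imbalance; each pair is therefore compared at
equal effort by repeatedly drawing min(n_i, n_j) records without replacement
from both cells. Residual effort effects are modelled, not assumed away: the
distance-decay mixed model carries the least-sampled cell's record count,
the log effort ratio and their interaction as fixed covariates, with a
random intercept per focal cell.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "betasim",
    "equal_effort_similarity",
    "build_pair_table",
    "logit_similarity",
    "DecayModelFit",
    "fit_distance_decay",
    "predict_decay",
]


def betasim(a: int, b: int, c: int) -> float:
    """Replacement-component similarity from shared/unique species counts.

    a = species shared, b = unique to the first assemblage, c = unique to
    the second. Returns a / (a + min(b, c)): 1 under nestedness, 0 with no
    shared species.
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c == 0:
        raise ValueError("similarity undefined for two empty assemblages")
    if a == 0:
        return 0.0
    return a / (a + min(b, c))


def _canonical_order(ci: np.ndarray, cj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic ordering of the two count vectors.

    The subsampling loop consumes random numbers in a fixed order, so
    symmetry of the estimate in (i, j) is guaranteed by always drawing for
    the canonically-first vector first (betasim itself is symmetric).
    """
    ki = (int(ci.sum()), tuple(ci.tolist()))
    kj = (int(cj.sum()), tuple(cj.tolist()))
    return (ci, cj) if ki <= kj else (cj, ci)


def equal_effort_similarity(
    counts_i,
    counts_j,
    R: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Mean 1-betasim over R equal-effort subsamples of a cell pair.

    ``counts_i`` and ``counts_j`` are record counts aligned on a shared
    taxon axis. Each replicate draws m = min(n_i, n_j) records without
    replacement from both cells (multivariate hypergeometric), reduces to
    presence, and scores 1-betasim; the estimate is the replicate mean.
    Symmetric in (i, j) and deterministic given the seed.
    """
    if R < 1:
        raise ValueError("need at least one replicate")
    ci = np.asarray(counts_i, dtype=int)
    cj = np.asarray(counts_j, dtype=int)
    if ci.shape != cj.shape:
        raise ValueError("count vectors must share a taxon axis")
    ni, nj = int(ci.sum()), int(cj.sum())
    if ni < 1 or nj < 1:
        raise ValueError("both cells need records")
    m = min(ni, nj)
    first, second = _canonical_order(ci, cj)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = np.empty(R)
    for r in range(R):
        sub1 = rng.multivariate_hypergeometric(first, m)
        sub2 = rng.multivariate_hypergeometric(second, m)
        p1 = sub1 > 0
        p2 = sub2 > 0
        a = int((p1 & p2).sum())
        b = int((p1 & ~p2).sum())
        c = int((~p1 & p2).sum())
        sims[r] = betasim(a, b, c)
    return float(sims.mean())


def build_pair_table(
    table,
    period: str,
    cells: list[tuple[int, int]] | None = None,
    R: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Equal-effort similarity for every unordered cell pair in one period.

    ``table`` is an :class:`~biotrend.records.AssemblageTable`. Pairs are
    enumerated once (no repetition); the focal cell of a pair is the
    lexicographically smaller index. Covariates attached per pair: centroid
    distance (km), records of the least-sampled cell ``n_min`` and the log
    effort ratio ``rel_diff`` = ln(n_max / n_min). The per-pair random
    stream is keyed on (seed, period, pair), so results do not depend on
    enumeration order.
    """
    if cells is None:
        cells = table.cells(period)
    cells = sorted(cells)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to form pairs")
    size = table.grid.cell_size
    rows = []
    for ai in range(len(cells)):
        for bi in range(ai + 1, len(cells)):
            ca, cb = cells[ai], cells[bi]
            va, vb = table.aligned_counts(ca, cb, period)
            na, nb = int(va.sum()), int(vb.sum())
            dist = size * math.hypot(ca[0] - cb[0], ca[1] - cb[1])
            pair_key = zlib.crc32(f"{period}:{ca}:{cb}".encode())
            pair_seed = np.random.SeedSequence(
                entropy=0 if seed is None else seed, spawn_key=(pair_key,)
            )
            sim = equal_effort_similarity(
                va, vb, R=R, seed=np.random.default_rng(pair_seed)
            )
            rows.append(
                {
                    "focal_ix": ca[0], "focal_iy": ca[1],
                    "other_ix": cb[0], "other_iy": cb[1],
                    "period": period,
                    "sim": sim,
                    "distance": dist,
                    "n_min": min(na, nb),
                    "rel_diff": math.log(max(na, nb) / min(na, nb)),
                    "replicates": R,
                }
            )
    return pd.DataFrame(rows)


def logit_similarity(sim: float | np.ndarray, n_replicates: int | None = None):
    """Empirical logit of a similarity in [0, 1].

    With N Monte-Carlo replicates the proportion is shrunk to
    s' = (s (N-1) + 0.5) / N before the logit, keeping boundary values
    finite at a scale tied to the Monte-Carlo resolution; ``None`` applies
    the plain logit.
    """
    s = np.asarray(sim, float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("similarity must lie in [0, 1]")
    if n_replicates is not None:
        N = n_replicates
        s = (s * (N - 1) + 0.5) / N
    out = np.log(s / (1.0 - s))
    return float(out) if np.isscalar(sim) or out.ndim == 0 else out


@dataclass
class DecayModelFit:
    """Distance-decay linear mixed model for logit similarity.

    Fixed effects: distance, period, distance x period, n_min, rel_diff and
    n_min x rel_diff; random intercept per focal cell. ML log-likelihood is
    reported for model comparison, coefficient estimates come from REML.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    group_var: float
    resid_var: float
    loglik_ml: float
    loglik_reml: float
    n_pairs: int
    n_groups: int
    periods: list[str]
    covariate_means: dict[str, float]
    converged: bool = True
    mixed: bool = True

    def period_effect(
        self, period: str, at_distance: float | None = None
    ) -> tuple[float, float, float]:
        """(estimate, se, p) of the period contrast vs the baseline period.

        With a distance x period interaction in the model the contrast
        depends on distance; it is evaluated at ``at_distance`` (default:
        the mean pair distance, the centre of the data — the main effect
        alone would be the contrast extrapolated to distance 0).
        """
        from scipy import stats as _stats

        d = self.covariate_means["distance"] if at_distance is None else at_distance
        main = f"C(period)[T.{period}]"
        inter = f"distance:C(period)[T.{period}]"
        est = float(self.params[main]) + d * float(self.params.get(inter, 0.0))
        var = float(self.cov_params.loc[main, main])
        if inter in self.params.index:
            var += d**2 * float(self.cov_params.loc[inter, inter])
            var += 2 * d * float(self.cov_params.loc[main, inter])
        se = math.sqrt(max(var, 0.0))
        z = est / se if se > 0 else float("inf")
        return est, se, float(2 * _stats.norm.sf(abs(z)))


_DECAY_FORMULA = "logit_sim ~ distance * C(period) + n_min + rel_diff + n_min:rel_diff"


def fit_distance_decay(pairs: pd.DataFrame, min_pairs: int = 20) -> DecayModelFit:
    """Fit the logit distance-decay mixed model across periods.

    ``pairs`` concatenates :func:`build_pair_table` outputs over >= 2
    periods; the response is the empirical logit of ``sim`` at each row's
    replicate count. Falls back to an OLS fixed-effects fit (flagged
    ``mixed=False``) if the random-intercept fit fails or is singular.
    """
    import statsmodels.formula.api as smf

    periods = sorted(pairs["period"].unique())
    if len(periods) < 2:
        raise ValueError("need pairs from at least 2 periods")
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {len(pairs)}")
    df = pairs.copy()
    df["logit_sim"] = [
        logit_similarity(s, int(n)) for s, n in zip(df["sim"], df["replicates"])
    ]
    df["focal"] = df["focal_ix"].astype(str) + "_" + df["focal_iy"].astype(str)

    import warnings

    mixed = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(_DECAY_FORMULA, df, groups=df["focal"])
            fit_reml = model.fit(reml=True)
            fit_ml = model.fit(reml=False)
        group_var = float(fit_reml.cov_re.iloc[0, 0])
        resid_var = float(fit_reml.scale)
        params = fit_reml.fe_params
        bse = fit_reml.bse_fe
        pvals = fit_reml.pvalues[params.index]
        cov = fit_reml.cov_params().loc[params.index, params.index]
        ll_ml, ll_reml = float(fit_ml.llf), float(fit_reml.llf)
        converged = bool(fit_reml.converged)
        if not converged or bse.isna().any() or not np.isfinite(params).all():
            mixed = False
    except Exception:
        mixed = False
    if not mixed:
        ols = smf.ols(_DECAY_FORMULA, df).fit()
        params, bse, pvals = ols.params, ols.bse, ols.pvalues
        cov = ols.cov_params()
        group_var, resid_var = 0.0, float(ols.mse_resid)
        ll_ml = ll_reml = float(ols.llf)
        converged = True
        mixed = False
    means = {
        "n_min": float(df["n_min"].mean()),
        "rel_diff": float(df["rel_diff"].mean()),
        "distance": float(df["distance"].mean()),
    }
    return DecayModelFit(
        params, bse, pvals, pd.DataFrame(cov), group_var, resid_var,
        ll_ml, ll_reml, len(df), df["focal"].nunique(), periods, means,
        converged=converged, mixed=mixed,
    )


def predict_decay(
    fit: DecayModelFit, distances: np.ndarray, period: str
) -> pd.DataFrame:
    """Covariate-adjusted decay curve with 95% CI for one period.

    Effort covariates are held at their sample means (the "after removing
    the effect of sampling effort" view); the CI reflects fixed-effect
    uncertainty only. Returns logit-scale fit and back-transformed
    similarity columns.
    """
    distances = np.asarray(distances, float)
    names = list(fit.params.index)
    X = np.zeros((len(distances), len(names)))
    base = fit.periods[0]

    def set_col(name: str, value: np.ndarray | float):
        if name in names:
            X[:, names.index(name)] = value

    set_col("Intercept", 1.0)
    set_col("distance", distances)
    set_col("n_min", fit.covariate_means["n_min"])
    set_col("rel_diff", fit.covariate_means["rel_diff"])
    set_col("n_min:rel_diff", fit.covariate_means["n_min"] * fit.covariate_means["rel_diff"])
    if period != base:
        set_col(f"C(period)[T.{period}]", 1.0)
        set_col(f"distance:C(period)[T.{period}]", distances)
    beta = fit.params.to_numpy()
    eta = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_params.to_numpy(), X))
    lo, hi = eta - 1.96 * se, eta + 1.96 * se
    inv = lambda t: 1.0 / (1.0 + np.exp(-t))
    return pd.DataFrame(
        {
            "distance": distances,
            "period": period,
            "logit_fit": eta,
            "logit_lo": lo,
            "logit_hi": hi,
            "sim": inv(eta),
            "sim_lo": inv(lo),
            "sim_hi": inv(hi),
        }
    )
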