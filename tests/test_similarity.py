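import itertools
import math

import numpy as np
import pandas as pd
import pytest

from biotrend.records import AssemblageTable, GridSpec, assign_grid_cells
from biotrend.similarity import (
    betasim,
    build_pair_table,
    equal_effort_similarity,
    fit_distance_decay,
    logit_similarity,
    predict_decay,
)


class TestBetasim:
    def test_nested_is_one(self):
        assert betasim(5, 2, 0) == 1.0

    def test_disjoint_is_zero(self):
        assert betasim(0, 3, 4) == 0.0

    def test_direct_evaluation(self):
        assert betasim(4, 3, 2) == pytest.approx(2 / 3, abs=1e-9)

    def test_symmetric_in_unique_counts(self):
        assert betasim(4, 3, 2) == betasim(4, 2, 3)

    @pytest.mark.parametrize("a,b,c", list(itertools.product(range(4), repeat=3)))
    def test_matches_brute_force_set_construction(self, a, b, c):
        if a + b + c == 0:
            return
        s1 = set(range(a)) | {f"u{i}" for i in range(b)}
        s2 = set(range(a)) | {f"v{i}" for i in range(c)}
        aa = len(s1 & s2)
        bb = len(s1 - s2)
        cc = len(s2 - s1)
        expect = 0.0 if aa == 0 else aa / (aa + min(bb, cc))
        assert betasim(a, b, c) == pytest.approx(expect, abs=1e-12)

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            betasim(0, 0, 0)


def exact_equal_effort_expectation(counts_i, counts_j, m):
    """Exact E[1-betasim] under without-replacement subsampling of m records
    from each cell, by enumerating all record subsets of both cells."""
    def presences(counts):
        labels = [sp for sp, k in enumerate(counts) for _ in range(k)]
        out = {}
        for sub in itertools.combinations(range(len(labels)), m):
            key = frozenset(labels[i] for i in sub)
            out[key] = out.get(key, 0) + 1
        total = sum(out.values())
        return {k: v / total for k, v in out.items()}

    pi = presences(counts_i)
    pj = presences(counts_j)
    exp = 0.0
    for si, wi in pi.items():
        for sj, wj in pj.items():
            a = len(si & sj)
            b = len(si - sj)
            c = len(sj - si)
            exp += wi * wj * (0.0 if a == 0 else a / (a + min(b, c)))
    return exp


class TestEqualEffortSimilarity:
    def test_identical_assemblages_equal_counts(self):
        c = np.array([5, 3, 2])
        assert equal_effort_similarity(c, c, R=20, seed=0) == 1.0

    def test_disjoint_assemblages(self):
        ci = np.array([4, 3, 0, 0])
        cj = np.array([0, 0, 5, 2])
        assert equal_effort_similarity(ci, cj, R=20, seed=0) == 0.0

    def test_symmetry_same_seed(self):
        ci = np.array([6, 2, 1, 0, 0])
        cj = np.array([0, 3, 2, 4, 1])
        a = equal_effort_similarity(ci, cj, R=200, seed=5)
        b = equal_effort_similarity(cj, ci, R=200, seed=5)
        assert a == b

    def test_matches_exact_hypergeometric_enumeration(self):
        ci = np.array([2, 1, 1, 0])
        cj = np.array([1, 1, 0, 2])
        m = min(ci.sum(), cj.sum())
        exact = exact_equal_effort_expectation(ci, cj, m)
        R = 4000
        est = equal_effort_similarity(ci, cj, R=R, seed=77)
        # replicate SD of 1-betasim is at most 0.5; 2 MC SEs plus slack
        assert abs(est - exact) < 2 * 0.5 / math.sqrt(R) + 0.01

    def test_deep_equal_effort_converges_to_presence_betasim(self):
        # the estimate depends on the common effort m by construction; as
        # both cells are sampled ever deeper it must converge to the
        # betasim of the full presence sets
        ci = np.array([8, 4, 2, 1])
        cj = np.array([3, 0, 5, 2])
        a = int(((ci > 0) & (cj > 0)).sum())
        b = int(((ci > 0) & (cj == 0)).sum())
        c = int(((ci == 0) & (cj > 0)).sum())
        target = betasim(a, b, c)
        deep = equal_effort_similarity(50 * ci, 50 * cj, R=400, seed=9)
        shallow = equal_effort_similarity(ci, cj, R=400, seed=9)
        assert abs(deep - target) < 0.02
        assert abs(deep - target) <= abs(shallow - target)

    def test_rare_extra_species_barely_breaks_nestedness(self):
        base = np.array([50, 50, 0])
        extra = np.array([50, 50, 1])
        sim = equal_effort_similarity(base, extra, R=500, seed=3)
        assert sim > 0.97


class TestLogitSimilarity:
    def test_plain_logit(self):
        assert logit_similarity(2 / 3) == pytest.approx(math.log(2), abs=1e-9)

    def test_boundary_rule_at_one(self):
        # s' = (1 * 99 + 0.5)/100 = 0.995 -> logit = ln(199) = 5.293
        assert logit_similarity(1.0, 100) == pytest.approx(5.293, abs=1e-3)

    def test_midpoint_fixed_for_any_replicates(self):
        for N in (10, 100, 1000):
            assert logit_similarity(0.5, N) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit_similarity(1.2)


def _toy_table():
    rng = np.random.default_rng(4)
    rows = []
    for (ix, iy), n in zip([(0, 0), (1, 0), (0, 1), (2, 2)], [30, 30, 60, 45]):
        taxa = rng.choice([f"t{i}" for i in range(12)], size=n)
        for t in taxa:
            rows.append({"taxon": t, "x": ix * 10 + 5.0, "y": iy * 10 + 5.0, "year": 1955})
    recs = pd.DataFrame(rows)
    grid = GridSpec(10.0, periods={"P1": (1950, 1969), "P2": (1970, 1989)})
    gridded, _ = assign_grid_cells(recs, grid)
    return AssemblageTable.from_records(gridded, grid)


class TestBuildPairTable:
    def test_four_cells_six_pairs(self):
        pairs = build_pair_table(_toy_table(), "P1", R=10, seed=0)
        assert len(pairs) == 6

    def test_rel_diff_zero_for_equal_efforts(self):
        pairs = build_pair_table(_toy_table(), "P1", R=10, seed=0)
        row = pairs[
            (pairs["focal_ix"] == 0) & (pairs["focal_iy"] == 0)
            & (pairs["other_ix"] == 1) & (pairs["other_iy"] == 0)
        ].iloc[0]
        assert row["rel_diff"] == pytest.approx(0.0, abs=1e-12)
        assert row["n_min"] == 30
        assert row["distance"] == pytest.approx(10.0)

    def test_distances_form_a_metric(self):
        pairs = build_pair_table(_toy_table(), "P1", R=5, seed=0)
        d = {}
        for _, r in pairs.iterrows():
            key = frozenset([(r["focal_ix"], r["focal_iy"]), (r["other_ix"], r["other_iy"])])
            d[key] = r["distance"]
        cells = [(0, 0), (1, 0), (0, 1), (2, 2)]
        for a, b, c in itertools.permutations(cells, 3):
            assert d[frozenset([a, b])] <= d[frozenset([a, c])] + d[frozenset([c, b])] + 1e-9

    def test_pair_results_independent_of_enumeration_order(self):
        table = _toy_table()
        all_pairs = build_pair_table(table, "P1", R=50, seed=1)
        subset = build_pair_table(table, "P1", cells=[(0, 0), (2, 2)], R=50, seed=1)
        key = ["focal_ix", "focal_iy", "other_ix", "other_iy"]
        merged = subset.merge(all_pairs, on=key, suffixes=("_sub", "_all"))
        np.testing.assert_allclose(merged["sim_sub"], merged["sim_all"])


def _synthetic_pairs(rng, n_cells=12, slope=-0.5, period_shift=0.0, rel_diff_coef=0.0,
                     noise=0.3, N=2000):
    """Pair rows drawn from a known logit-linear decay model."""
    side = int(math.ceil(math.sqrt(n_cells)))
    cells = [(i, j) for i in range(side) for j in range(side)][:n_cells]
    efforts = {c: int(rng.integers(200, 800)) for c in cells}
    focal_eff = {c: rng.normal(0, 0.2) for c in cells}
    rows = []
    for period, shift in (("P1", 0.0), ("P2", period_shift)):
        for a, b in itertools.combinations(cells, 2):
            # distances in cell units keep logits off the boundary for the
            # O(1) slopes used in these recovery checks
            dist = math.hypot(a[0] - b[0], a[1] - b[1])
            na, nb = efforts[a], efforts[b]
            rel = math.log(max(na, nb) / min(na, nb))
            eta = 2.0 + slope * dist + shift + rel_diff_coef * rel
            eta += focal_eff[a] + rng.normal(0, noise)
            sim = 1 / (1 + math.exp(-eta))
            rows.append(
                {
                    "focal_ix": a[0], "focal_iy": a[1],
                    "other_ix": b[0], "other_iy": b[1],
                    "period": period, "sim": sim,
                    "distance": dist, "n_min": min(na, nb),
                    "rel_diff": rel, "replicates": N,
                }
            )
    return pd.DataFrame(rows)


class TestDistanceDecayModel:
    def test_slope_recovered_from_known_generator(self):
        rng = np.random.default_rng(21)
        pairs = _synthetic_pairs(rng, slope=-0.5)
        fit = fit_distance_decay(pairs)
        est = fit.params["distance"]
        se = fit.bse["distance"]
        assert est - 1.96 * se <= -0.5 <= est + 1.96 * se

    def test_period_shift_detected_as_homogenisation(self):
        rng = np.random.default_rng(22)
        pairs = _synthetic_pairs(rng, period_shift=0.8)
        fit = fit_distance_decay(pairs)
        eff, se, p = fit.period_effect("P2")
        assert eff > 0
        assert p < 0.01

    def test_prediction_curves_ordered_by_period_effect(self):
        rng = np.random.default_rng(23)
        pairs = _synthetic_pairs(rng, period_shift=0.8)
        fit = fit_distance_decay(pairs)
        d = np.linspace(0, 3, 7)
        c1 = predict_decay(fit, d, "P1")
        c2 = predict_decay(fit, d, "P2")
        assert (c2["sim"].to_numpy() > c1["sim"].to_numpy()).mean() > 0.8

    def test_needs_two_periods(self):
        rng = np.random.default_rng(24)
        pairs = _synthetic_pairs(rng)
        with pytest.raises(ValueError, match="period"):
            fit_distance_decay(pairs[pairs["period"] == "P1"])
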