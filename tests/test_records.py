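import numpy as np
import pandas as pd
import pytest

from biotrend.records import (
    AssemblageTable,
    GridSpec,
    SelectionCriteria,
    apply_aggregation,
    assign_grid_cells,
    coarsen_cells,
    filter_cells,
    parse_records,
    resolve_aggregation_map,
    tabulate_assemblages,
)
from biotrend.simulate import SimConfig, generate_landscape, sample_records


class TestParse:
    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "recs.csv"
        p.write_text("taxon,x,y,year\nA,1.0,2.0,1955\nB,3.0,4.0,1960\nC,5.0,6.0,1971\n")
        recs, report = parse_records(p)
        assert len(recs) == 3
        assert report.n_rejected == 0

    def test_unparseable_year_dropped_and_counted(self, tmp_path):
        p = tmp_path / "recs.csv"
        p.write_text("taxon,x,y,year\nA,1.0,2.0,19xx\nB,3.0,4.0,1960\n")
        recs, report = parse_records(p)
        assert len(recs) == 1
        assert report.n_rejected == 1
        assert report.reasons.get("bad_year") == 1

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "recs.csv"
        p.write_text("taxon,x,y\nA,1.0,2.0\n")
        with pytest.raises(KeyError):
            parse_records(p)

    def test_schema_mapping(self, tmp_path):
        p = tmp_path / "recs.tsv"
        p.write_text("name\teast\tnorth\tyr\nA\t1.0\t2.0\t1955\n")
        recs, _ = parse_records(p, schema={"taxon": "name", "x": "east", "y": "north", "year": "yr"})
        assert recs.loc[0, "taxon"] == "A"
        assert recs.loc[0, "year"] == 1955

    def test_generator_output_round_trips(self, tmp_path, small_landscape):
        _, _, records, _ = small_landscape
        p = tmp_path / "sim.csv"
        records.to_csv(p, index=False)
        parsed, report = parse_records(p)
        assert report.n_rejected == 0
        pd.testing.assert_frame_equal(
            parsed.sort_values(["taxon", "x"]).reset_index(drop=True),
            records.sort_values(["taxon", "x"]).reset_index(drop=True),
            check_dtype=False,
        )


class TestAggregation:
    def test_lumping(self):
        recs = pd.DataFrame({"taxon": ["A", "B", "C"], "x": [0.0] * 3, "y": [0.0] * 3, "year": [1955] * 3})
        out = apply_aggregation(recs, {"A": "AB", "B": "AB"})
        assert set(out["taxon"]) == {"AB", "C"}
        assert len(out) == 3  # record count unchanged

    def test_empty_map_is_identity(self):
        recs = pd.DataFrame({"taxon": ["A", "B"], "x": [0.0, 0.0], "y": [0.0, 0.0], "year": [1955, 1955]})
        out = apply_aggregation(recs, {})
        assert list(out["taxon"]) == ["A", "B"]

    def test_chain_resolved_to_fixed_point(self):
        resolved = resolve_aggregation_map({"A": "B", "B": "C"})
        assert resolved == {"A": "C", "B": "C"}
        # applying twice equals applying once
        recs = pd.DataFrame({"taxon": ["A", "B", "C"], "x": [0.0] * 3, "y": [0.0] * 3, "year": [1955] * 3})
        once = apply_aggregation(recs, {"A": "B", "B": "C"})
        twice = apply_aggregation(once, {"A": "B", "B": "C"})
        pd.testing.assert_frame_equal(once, twice)

    def test_cycle_is_load_error(self):
        with pytest.raises(ValueError, match="cycle"):
            resolve_aggregation_map({"A": "B", "B": "A"})

    def test_distinct_taxa_never_increase(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in rng.integers(0, 20, 50)]
        recs = pd.DataFrame({"taxon": taxa, "x": [0.0] * 50, "y": [0.0] * 50, "year": [1955] * 50})
        mapping = {f"t{i}": f"g{i % 5}" for i in range(10)}
        out = apply_aggregation(recs, mapping)
        assert out["taxon"].nunique() <= recs["taxon"].nunique()


class TestGridding:
    def test_boundary_belongs_to_upper_cell(self, grid):
        recs = pd.DataFrame({"taxon": ["A"], "x": [10.0], "y": [0.0], "year": [1955]})
        out, _ = assign_grid_cells(recs, grid)
        assert out.loc[0, "cell_ix"] == 1

    def test_period_bounds_inclusive(self, grid):
        recs = pd.DataFrame(
            {"taxon": ["A", "B"], "x": [1.0, 1.0], "y": [1.0, 1.0], "year": [1969, 1970]}
        )
        out, _ = assign_grid_cells(recs, grid)
        assert list(out["period"]) == ["P1", "P2"]

    def test_out_of_period_dropped_and_counted(self, grid):
        recs = pd.DataFrame({"taxon": ["A", "B"], "x": [1.0, 1.0], "y": [1.0, 1.0], "year": [1900, 1955]})
        out, dropped = assign_grid_cells(recs, grid)
        assert dropped == 1
        assert len(out) == 1

    def test_coarsening_matches_direct_assignment(self, grid, small_landscape):
        _, _, records, _ = small_landscape
        fine, _ = assign_grid_cells(records, grid)
        tab_fine = tabulate_assemblages(fine)
        via_coarsen = coarsen_cells(tab_fine, 2)
        direct, _ = assign_grid_cells(records, grid.coarsen(2))
        tab_direct = tabulate_assemblages(direct)
        key = ["cell_ix", "cell_iy", "period", "taxon"]
        pd.testing.assert_frame_equal(
            via_coarsen.sort_values(key).reset_index(drop=True),
            tab_direct.sort_values(key).reset_index(drop=True),
        )

    def test_aggregation_and_gridding_commute(self, grid, tiny_records):
        mapping = {"A": "AB", "B": "AB"}
        a, _ = assign_grid_cells(apply_aggregation(tiny_records, mapping), grid)
        b_pre, _ = assign_grid_cells(tiny_records, grid)
        b = apply_aggregation(b_pre, mapping)
        pd.testing.assert_frame_equal(a, b)


class TestTabulate:
    def test_counts_and_rarity_classes(self, grid):
        recs = pd.DataFrame(
            {"taxon": ["A", "A", "B"], "x": [1.0] * 3, "y": [1.0] * 3, "year": [1955] * 3}
        )
        gridded, _ = assign_grid_cells(recs, grid)
        table = AssemblageTable.from_records(gridded, grid)
        summ = table.summary()
        assert len(summ) == 1
        row = summ.iloc[0]
        assert (row["n"], row["s_obs"], row["f1"], row["f2"]) == (3, 2, 1, 1)

    def test_record_conservation_against_generator_truth(self, grid, small_landscape):
        _, _, records, effort = small_landscape
        gridded, dropped = assign_grid_cells(records, grid)
        assert dropped == 0
        table = AssemblageTable.from_records(gridded, grid)
        summ = table.summary().set_index(["cell_ix", "cell_iy", "period"])["n"]
        eff = effort.set_index(["cell_ix", "cell_iy", "period"])["n_records"]
        eff = eff[eff > 0]
        assert summ.sort_index().equals(eff.sort_index().astype(summ.dtype))


class TestFilterCells:
    def _table(self, grid):
        cfg = SimConfig(grid_nx=4, grid_ny=4, n_species=80, effort_mean=100.0,
                        effort_sigma=0.8, seed=5)
        truth = generate_landscape(cfg)
        records, _ = sample_records(truth)
        gridded, _ = assign_grid_cells(records, grid)
        return AssemblageTable.from_records(gridded, grid)

    def test_both_periods_must_qualify(self, grid):
        recs = pd.DataFrame(
            {
                "taxon": ["A"] * 60 + ["B"] * 40,
                "x": [1.0] * 100,
                "y": [1.0] * 100,
                "year": [1955] * 60 + [1975] * 40,
            }
        )
        gridded, _ = assign_grid_cells(recs, grid)
        table = AssemblageTable.from_records(gridded, grid)
        with pytest.raises(ValueError, match="no analyzable cells"):
            filter_cells(table, ("P1", "P2"), SelectionCriteria(min_records=50))

    def test_zero_threshold_is_identity(self, grid):
        table = self._table(grid)
        kept, audit = filter_cells(table, ("P1", "P2"), SelectionCriteria(min_records=0))
        both = set(table.cells("P1")) & set(table.cells("P2"))
        assert set(kept) == both

    def test_tightening_is_monotone(self, grid):
        table = self._table(grid)
        loose, _ = filter_cells(table, ("P1", "P2"), SelectionCriteria(min_records=20))
        strict, _ = filter_cells(table, ("P1", "P2"), SelectionCriteria(min_records=80))
        assert set(strict) <= set(loose)

    def test_audit_log_reports_exclusions(self, grid):
        table = self._table(grid)
        kept, audit = filter_cells(table, ("P1", "P2"), SelectionCriteria(min_records=80))
        all_cells = set(table.cells("P1")) | set(table.cells("P2"))
        assert len(kept) + len(audit) == len(all_cells)
        assert (audit["reason"].str.len() > 0).all()
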