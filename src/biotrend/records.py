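"""Occurrence-record ingestion: parsing, taxon aggregation, gridding, tabulation.

The atomic input is a dated, georeferenced record of an (aggregate) taxon on a
planar grid in km. Records are carried as a pandas DataFrame with columns
``taxon``, ``x``, ``y``, ``year`` (plus optional ``source_id``); every
operation here is a plain function DataFrame -> DataFrame so the stages
compose and commute where they should (aggregation touches only ``taxon``,
gridding only ``x``/``y``/``year``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PERIODS",
    "GridSpec",
    "SelectionCriteria",
    "AssemblageTable",
    "ParseReport",
    "parse_records",
    "load_aggregation_map",
    "resolve_aggregation_map",
    "apply_aggregation",
    "assign_grid_cells",
    "coarsen_cells",
    "tabulate_assemblages",
    "filter_cells",
]

#: Twenty-year study periods (inclusive calendar-year bounds).
DEFAULT_PERIODS: dict[str, tuple[int, int]] = {
    "P0": (1930, 1949),
    "P1": (1950, 1969),
    "P2": (1970, 1989),
    "P3": (1990, 2009),
}

RECORD_COLUMNS = ["taxon", "x", "y", "year"]


@dataclass(frozen=True)
class GridSpec:
    """Planar analysis grid plus the temporal binning.

    Parameters
    ----------
    cell_size : float
        Cell edge length in km (e.g. 10, 20, 40, 80, 160).
    origin : tuple of float
        Lower-left corner (x0, y0) in km. Cells are half-open
        ``[edge, edge + cell_size)`` so a record exactly on a boundary
        belongs to the upper cell.
    periods : mapping
        Ordered period name -> (start_year, end_year), inclusive on both
        ends, non-overlapping.
    """

    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    periods: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PERIODS)
    )

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        bounds = list(self.periods.values())
        for (s, e) in bounds:
            if s > e:
                raise ValueError(f"period start {s} after end {e}")
        for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
            if not e1 < s2:
                raise ValueError("periods must be ordered and non-overlapping")

    def period_of(self, year: np.ndarray) -> np.ndarray:
        """Vectorised year -> period name ('' if outside all periods)."""
        out = np.full(len(year), "", dtype=object)
        for name, (s, e) in self.periods.items():
            out[(year >= s) & (year <= e)] = name
        return out

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid with cells ``factor`` times larger, same origin and periods."""
        if factor < 1 or factor != int(factor):
            raise ValueError("factor must be a positive integer")
        return GridSpec(self.cell_size * factor, self.origin, dict(self.periods))

    def centroid(self, ix: np.ndarray, iy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        return (
            x0 + (np.asarray(ix) + 0.5) * self.cell_size,
            y0 + (np.asarray(iy) + 0.5) * self.cell_size,
        )


@dataclass
class ParseReport:
    """Bookkeeping from :func:`parse_records`."""

    n_read: int
    n_kept: int
    n_rejected: int
    reasons: dict[str, int]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)


def parse_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    year_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read occurrence records from a delimited text file.

    ``schema`` maps the canonical field names (``taxon``, ``x``, ``y``,
    ``year``, optionally ``source_id``) to the column names in the file;
    identity mapping by default. Rows whose year or coordinates fail to
    parse (or fall outside ``year_range``) are dropped and counted in the
    returned :class:`ParseReport`.
    """
    raw = _read_delimited(path)
    schema = dict(schema or {})
    colmap = {f: schema.get(f, f) for f in RECORD_COLUMNS}
    missing = [c for c in colmap.values() if c not in raw.columns]
    if missing:
        raise KeyError(f"missing mandatory column(s): {missing}")

    n_read = len(raw)
    reasons: dict[str, int] = {}
    df = pd.DataFrame(
        {
            "taxon": raw[colmap["taxon"]].astype(str).str.strip(),
            "x": pd.to_numeric(raw[colmap["x"]], errors="coerce"),
            "y": pd.to_numeric(raw[colmap["y"]], errors="coerce"),
            "year": pd.to_numeric(raw[colmap["year"]], errors="coerce"),
        }
    )
    src_col = schema.get("source_id")
    if src_col and src_col in raw.columns:
        df["source_id"] = raw[src_col]

    bad_taxon = df["taxon"].isin(["", "nan"])
    bad_coord = ~(np.isfinite(df["x"]) & np.isfinite(df["y"]))
    bad_year = df["year"].isna() | (df["year"] % 1 != 0)
    if year_range is not None:
        lo, hi = year_range
        bad_year |= (df["year"] < lo) | (df["year"] > hi)
    for name, mask in [
        ("bad_taxon", bad_taxon),
        ("bad_coordinates", bad_coord & ~bad_taxon),
        ("bad_year", bad_year & ~bad_taxon & ~bad_coord),
    ]:
        if mask.any():
            reasons[name] = int(mask.sum())
    keep = ~(bad_taxon | bad_coord | bad_year)
    out = df.loc[keep].reset_index(drop=True)
    out["year"] = out["year"].astype(int)
    report = ParseReport(n_read, len(out), n_read - len(out), reasons)
    return out, report


def resolve_aggregation_map(mapping: Mapping[str, str]) -> dict[str, str]:
    """Resolve a raw->aggregate name map to its fixed point.

    Chains (A -> B, B -> C) collapse to their terminal name so that applying
    the resolved map is idempotent; cycles raise at load time.
    """
    resolved: dict[str, str] = {}
    for start in mapping:
        seen = [start]
        cur = start
        while cur in mapping and mapping[cur] != cur:
            cur = mapping[cur]
            if cur in seen:
                raise ValueError(f"aggregation map contains a cycle: {' -> '.join(seen + [cur])}")
            seen.append(cur)
        resolved[start] = cur
    return resolved


def load_aggregation_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (raw_name, aggregate_name) CSV/TSV and resolve chains."""
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError("aggregation map needs two columns: raw name, aggregate name")
    raw_col, agg_col = df.columns[:2]
    return resolve_aggregation_map(
        dict(zip(df[raw_col].astype(str).str.strip(), df[agg_col].astype(str).str.strip()))
    )


def apply_aggregation(records: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Lump raw taxon names into aggregate taxa; unmapped names pass through."""
    resolved = resolve_aggregation_map(mapping)
    out = records.copy()
    out["taxon"] = out["taxon"].map(lambda t: resolved.get(t, t))
    return out


def assign_grid_cells(
    records: pd.DataFrame, grid: GridSpec
) -> tuple[pd.DataFrame, int]:
    """Tag records with (cell_ix, cell_iy, period); drop out-of-period records.

    Cell indices follow ``floor((coord - origin) / cell_size)`` with half-open
    cells, so a coordinate exactly on a boundary belongs to the upper cell.
    Returns the tagged frame and the count of records outside every period.
    """
    out = records.copy()
    x0, y0 = grid.origin
    out["cell_ix"] = np.floor((out["x"].to_numpy() - x0) / grid.cell_size).astype(int)
    out["cell_iy"] = np.floor((out["y"].to_numpy() - y0) / grid.cell_size).astype(int)
    out["period"] = grid.period_of(out["year"].to_numpy())
    dropped = int((out["period"] == "").sum())
    out = out[out["period"] != ""].reset_index(drop=True)
    return out, dropped


def coarsen_cells(table: pd.DataFrame, factor: int) -> pd.DataFrame:
    """Re-index a tabulated assemblage table onto a grid ``factor``× coarser.

    Operates on the long table from :func:`tabulate_assemblages`; counts of
    constituent fine cells sum into the containing coarse cell.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = table.copy()
    out["cell_ix"] = out["cell_ix"] // factor
    out["cell_iy"] = out["cell_iy"] // factor
    return (
        out.groupby(["cell_ix", "cell_iy", "period", "taxon"], as_index=False)["count"]
        .sum()
    )


def tabulate_assemblages(records: pd.DataFrame) -> pd.DataFrame:
    """Count records per (cell, period, taxon) -> long assemblage table."""
    for col in ("cell_ix", "cell_iy", "period"):
        if col not in records.columns:
            raise KeyError("records must be gridded first (assign_grid_cells)")
    table = (
        records.groupby(["cell_ix", "cell_iy", "period", "taxon"])
        .size()
        .rename("count")
        .reset_index()
    )
    return table


class AssemblageTable:
    """Per-(cell, period) taxon record counts with derived summaries.

    Wraps the long count table and exposes the quantities every estimator
    needs: n (records), S_obs (observed taxa), f1 (singletons), f2
    (doubletons) per cell-period, and aligned count vectors for cell pairs.
    """

    def __init__(self, table: pd.DataFrame, grid: GridSpec):
        if (table["count"] < 0).any():
            raise ValueError("negative counts")
        self.table = table.reset_index(drop=True)
        self.grid = grid

    @classmethod
    def from_records(cls, records: pd.DataFrame, grid: GridSpec) -> "AssemblageTable":
        return cls(tabulate_assemblages(records), grid)

    def coarsen(self, factor: int) -> "AssemblageTable":
        return AssemblageTable(coarsen_cells(self.table, factor), self.grid.coarsen(factor))

    def pool_all(self) -> "AssemblageTable":
        """Union of all cells as one 'country' cell (index 0,0)."""
        pooled = self.table.copy()
        pooled["cell_ix"] = 0
        pooled["cell_iy"] = 0
        pooled = pooled.groupby(
            ["cell_ix", "cell_iy", "period", "taxon"], as_index=False
        )["count"].sum()
        big = GridSpec(1e9, self.grid.origin, dict(self.grid.periods))
        return AssemblageTable(pooled, big)

    def summary(self) -> pd.DataFrame:
        """Per (cell, period): n, S_obs, f1, f2."""
        g = self.table.groupby(["cell_ix", "cell_iy", "period"])["count"]
        out = g.agg(
            n="sum",
            s_obs="count",
            f1=lambda c: int((c == 1).sum()),
            f2=lambda c: int((c == 2).sum()),
        ).reset_index()
        return out

    def cells(self, period: str | None = None) -> list[tuple[int, int]]:
        t = self.table if period is None else self.table[self.table["period"] == period]
        return sorted(set(zip(t["cell_ix"], t["cell_iy"])))

    def counts(self, cell: tuple[int, int], period: str) -> np.ndarray:
        """Abundance vector (record counts per taxon) for one cell-period."""
        m = (
            (self.table["cell_ix"] == cell[0])
            & (self.table["cell_iy"] == cell[1])
            & (self.table["period"] == period)
        )
        return self.table.loc[m, "count"].to_numpy(dtype=int)

    def aligned_counts(
        self, cell_a: tuple[int, int], cell_b: tuple[int, int], period: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Counts for two cells on a shared taxon axis (for similarity)."""
        t = self.table[self.table["period"] == period]
        sub = t[
            ((t["cell_ix"] == cell_a[0]) & (t["cell_iy"] == cell_a[1]))
            | ((t["cell_ix"] == cell_b[0]) & (t["cell_iy"] == cell_b[1]))
        ]
        pivot = (
            sub.assign(is_a=(sub["cell_ix"] == cell_a[0]) & (sub["cell_iy"] == cell_a[1]))
            .pivot_table(index="taxon", columns="is_a", values="count", aggfunc="sum", fill_value=0)
        )
        a = pivot[True].to_numpy(int) if True in pivot.columns else np.zeros(len(pivot), int)
        b = pivot[False].to_numpy(int) if False in pivot.columns else np.zeros(len(pivot), int)
        return a, b

    def centroids(self) -> pd.DataFrame:
        cells = self.cells()
        ix = np.array([c[0] for c in cells])
        iy = np.array([c[1] for c in cells])
        cx, cy = self.grid.centroid(ix, iy)
        return pd.DataFrame({"cell_ix": ix, "cell_iy": iy, "cx": cx, "cy": cy})


@dataclass(frozen=True)
class SelectionCriteria:
    """A-priori exclusion of poorly sampled cells.

    A cell qualifies for a period pair only if *both* periods meet every
    threshold. Defaults are documented stand-ins: >=50 records per
    cell-period for richness analyses and a stricter >=200 for similarity
    analyses, where species identity matters more.
    """

    min_records: int = 50
    min_taxa: int = 1

    def qualifies(self, n: int, s_obs: int) -> bool:
        return n >= self.min_records and s_obs >= self.min_taxa


RICHNESS_CRITERIA = SelectionCriteria(min_records=50)
SIMILARITY_CRITERIA = SelectionCriteria(min_records=200)


def filter_cells(
    table: AssemblageTable,
    period_pair: tuple[str, str],
    criteria: SelectionCriteria = RICHNESS_CRITERIA,
) -> tuple[list[tuple[int, int]], pd.DataFrame]:
    """Select cells where both periods of ``period_pair`` pass ``criteria``.

    Returns the retained cell list and an audit log with one row per
    excluded cell and the reason. Raises if nothing survives.
    """
    summ = table.summary()
    p1, p2 = period_pair
    wide = summ[summ["period"].isin(period_pair)]
    kept: list[tuple[int, int]] = []
    audit_rows = []
    for cell, sub in wide.groupby(["cell_ix", "cell_iy"]):
        by_period = {r["period"]: r for _, r in sub.iterrows()}
        reasons = []
        for p in period_pair:
            if p not in by_period:
                reasons.append(f"{p}: no records")
            elif not criteria.qualifies(by_period[p]["n"], by_period[p]["s_obs"]):
                reasons.append(
                    f"{p}: n={int(by_period[p]['n'])} below thresholds"
                )
        if reasons:
            audit_rows.append(
                {"cell_ix": cell[0], "cell_iy": cell[1], "reason": "; ".join(reasons)}
            )
        else:
            kept.append((int(cell[0]), int(cell[1])))
    audit = pd.DataFrame(audit_rows, columns=["cell_ix", "cell_iy", "reason"])
    if not kept:
        raise ValueError(
            f"no analyzable cells for {p1} vs {p2} under criteria {criteria}"
        )
    return kept, audit
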