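"""Synthetic occurrence landscapes with known richness change and homogenisation.

The generator emulates the statistical structure that unstandardised
collection data impose on the estimators: strongly skewed (lognormal)
species abundances so that assemblages carry singletons and doubletons,
spatially structured ranges (discs on a torus, so no edge-driven richness
gradients), lognormal per-cell sampling effort with a configurable
between-period imbalance, and two period-2 treatments of known magnitude —
per-cell random species loss (``extinction_fraction``) and ubiquitous spread
of the top-k commonest species (``expansion_k``, the homogenisation knob).
Truth tables (per-cell richness, logratio, pairwise 1-betasim) are computed
from the noise-free presence matrices and are invariant to the effort model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import DEFAULT_PERIODS
from .similarity import betasim

__all__ = ["SimConfig", "SimTruth", "generate_landscape", "sample_records", "truth_report"]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic landscape; all randomness flows from ``seed``."""

    grid_nx: int = 10
    grid_ny: int = 10
    cell_size: float = 10.0  # km
    n_species: int = 200
    #: lognormal relative-abundance distribution (mean/sd on the log scale);
    #: sigma 1.5 keeps plenty of rare species so sampled cells have singletons
    abund_mu: float = 0.0
    abund_sigma: float = 1.5
    #: per-species range-disc radius ~ lognormal, in km
    range_mu: float = math.log(20.0)
    range_sigma: float = 0.6
    periods: tuple[str, ...] = ("P1", "P2")
    #: per-cell species loss in the 2nd period: with mode "random" each
    #: species is lost independently with this probability (per-cell change
    #: varies binomially); with "fixed_fraction" exactly round(f * S) random
    #: species are removed per cell (uniform per-cell change)
    extinction_fraction: float = 0.0
    extinction_mode: str = "random"
    #: the k globally commonest species become ubiquitous in the 2nd period
    expansion_k: int = 0
    #: records per cell-period ~ lognormal(log(effort_mean), effort_sigma);
    #: the default emulates well-recorded atlas cells (order 10^3 records
    #: per cell-period, as in national recording schemes), comfortably above
    #: both selection thresholds; shallow-effort regimes are exercised by
    #: configuring this down
    effort_mean: float = 2000.0
    effort_sigma: float = 0.4
    #: multiplier on the 2nd (and later) periods' mean effort
    effort_imbalance: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_nx < 1 or self.grid_ny < 1 or self.n_species < 1:
            raise ValueError("grid and species pool must be non-empty")
        if not 0.0 <= self.extinction_fraction <= 1.0:
            raise ValueError("extinction_fraction must lie in [0, 1]")
        if not 0 <= self.expansion_k <= self.n_species:
            raise ValueError("expansion_k must lie in [0, n_species]")
        if self.extinction_mode not in ("random", "fixed_fraction"):
            raise ValueError("extinction_mode must be 'random' or 'fixed_fraction'")
        if len(self.periods) < 2:
            raise ValueError("need at least two periods")
        for p in self.periods:
            if p not in DEFAULT_PERIODS:
                raise ValueError(f"unknown period {p!r}")


@dataclass
class SimTruth:
    """Noise-free landscape state: presence and local abundance per period."""

    config: SimConfig
    species: list[str]
    #: per period: boolean (n_cells, n_species) presence matrix
    presence: dict[str, np.ndarray]
    #: per period: (n_cells, n_species) local relative abundances
    abundance: dict[str, np.ndarray]
    cell_index: pd.DataFrame  # cell_ix, cell_iy per row of the matrices

    @property
    def n_cells(self) -> int:
        return len(self.cell_index)

    def richness(self, period: str) -> np.ndarray:
        return self.presence[period].sum(axis=1)

    def true_logratio(self) -> pd.DataFrame:
        """ln(S2/S1) per cell between the first two periods."""
        p1, p2 = self.config.periods[:2]
        s1 = self.richness(p1).astype(float)
        s2 = self.richness(p2).astype(float)
        out = self.cell_index.copy()
        with np.errstate(divide="ignore"):
            out["s1"], out["s2"] = s1, s2
            out["logratio"] = np.log(s2 / s1)
        return out

    def true_similarity(self, period: str) -> pd.DataFrame:
        """Pairwise 1-betasim of the true presence sets (no sampling)."""
        pres = self.presence[period]
        rows = []
        for i in range(self.n_cells):
            for j in range(i + 1, self.n_cells):
                a = int((pres[i] & pres[j]).sum())
                b = int((pres[i] & ~pres[j]).sum())
                c = int((~pres[i] & pres[j]).sum())
                rows.append(
                    {
                        "cell_i": i, "cell_j": j, "period": period,
                        "sim": betasim(a, b, c) if a + b + c else float("nan"),
                    }
                )
        return pd.DataFrame(rows)


def _torus_dist2(dx: np.ndarray, dy: np.ndarray, lx: float, ly: float) -> np.ndarray:
    dx = np.abs(dx) % lx
    dy = np.abs(dy) % ly
    dx = np.minimum(dx, lx - dx)
    dy = np.minimum(dy, ly - dy)
    return dx**2 + dy**2


def generate_landscape(config: SimConfig) -> SimTruth:
    """Place species ranges and derive per-period presence/abundance truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    nx, ny, size = config.grid_nx, config.grid_ny, config.cell_size
    lx, ly = nx * size, ny * size
    n_sp = config.n_species

    cx, cy = np.meshgrid(
        (np.arange(nx) + 0.5) * size, (np.arange(ny) + 0.5) * size, indexing="ij"
    )
    cx, cy = cx.ravel(), cy.ravel()
    cell_index = pd.DataFrame(
        {"cell_ix": np.repeat(np.arange(nx), ny), "cell_iy": np.tile(np.arange(ny), nx)}
    )

    centers_x = rng.uniform(0, lx, n_sp)
    centers_y = rng.uniform(0, ly, n_sp)
    radii = rng.lognormal(config.range_mu, config.range_sigma, n_sp)
    global_abund = rng.lognormal(config.abund_mu, config.abund_sigma, n_sp)

    d2 = _torus_dist2(cx[:, None] - centers_x[None, :], cy[:, None] - centers_y[None, :], lx, ly)
    presence1 = d2 <= radii[None, :] ** 2
    # a range always covers its nearest cell centroid, so every species occurs
    nearest = d2.argmin(axis=0)
    presence1[nearest, np.arange(n_sp)] = True

    periods = list(config.periods)
    presence: dict[str, np.ndarray] = {periods[0]: presence1}
    later = presence1.copy()
    if config.extinction_fraction > 0:
        if config.extinction_mode == "random":
            survive = rng.random(later.shape) >= config.extinction_fraction
            later = later & survive
        else:  # exactly round(f * S) species removed per cell
            for i in range(later.shape[0]):
                present = np.flatnonzero(later[i])
                k_loss = int(round(config.extinction_fraction * len(present)))
                if k_loss > 0:
                    lost = rng.choice(present, size=k_loss, replace=False)
                    later[i, lost] = False
    if config.expansion_k > 0:
        top = np.argsort(global_abund)[::-1][: config.expansion_k]
        later[:, top] = True
    # cells must stay non-empty for the estimators; keep the locally
    # commonest original species if extinction emptied a cell
    empty = ~later.any(axis=1)
    if empty.any():
        for i in np.flatnonzero(empty):
            cands = np.flatnonzero(presence1[i])
            later[i, cands[np.argmax(global_abund[cands])]] = True
    for p in periods[1:]:
        presence[p] = later

    abundance = {
        p: np.where(pres, global_abund[None, :], 0.0) for p, pres in presence.items()
    }
    species = [f"sp{i:04d}" for i in range(n_sp)]
    return SimTruth(config, species, presence, abundance, cell_index)


def sample_records(
    truth: SimTruth, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw haphazard occurrence records from the landscape truth.

    Per cell-period the record count comes from the effort model, then taxa
    are drawn multinomially by local relative abundance; coordinates are
    uniform within the cell and years uniform within the period. Returns the
    record table and an effort bookkeeping table (the drawn totals).
    """
    cfg = truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed, spawn_key=(1,))
    )
    size = cfg.cell_size
    recs: list[pd.DataFrame] = []
    effort_rows = []
    species = np.array(truth.species)
    for pi, period in enumerate(cfg.periods):
        y0, y1 = DEFAULT_PERIODS[period]
        mean = cfg.effort_mean * (cfg.effort_imbalance if pi > 0 else 1.0)
        abund = truth.abundance[period]
        for i in range(truth.n_cells):
            n = int(np.round(rng.lognormal(math.log(mean), cfg.effort_sigma)))
            effort_rows.append(
                {
                    "cell_ix": truth.cell_index["cell_ix"].iat[i],
                    "cell_iy": truth.cell_index["cell_iy"].iat[i],
                    "period": period,
                    "n_records": n,
                }
            )
            if n == 0:
                continue
            p = abund[i]
            tot = p.sum()
            if tot == 0:
                continue
            draws = rng.multinomial(n, p / tot)
            taxa = np.repeat(species, draws)
            ix = truth.cell_index["cell_ix"].iat[i]
            iy = truth.cell_index["cell_iy"].iat[i]
            recs.append(
                pd.DataFrame(
                    {
                        "taxon": taxa,
                        "x": ix * size + rng.uniform(0, size, n),
                        "y": iy * size + rng.uniform(0, size, n),
                        "year": rng.integers(y0, y1 + 1, n),
                    }
                )
            )
    records = (
        pd.concat(recs, ignore_index=True)
        if recs
        else pd.DataFrame(columns=["taxon", "x", "y", "year"])
    )
    return records, pd.DataFrame(effort_rows)


def truth_report(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write truth tables (richness, logratio, pairwise similarity) as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    rich = truth.cell_index.copy()
    for p in truth.config.periods:
        rich[f"richness_{p}"] = truth.richness(p)
    paths["richness"] = outdir / "truth_richness.csv"
    rich.to_csv(paths["richness"], index=False)
    paths["logratio"] = outdir / "truth_logratio.csv"
    truth.true_logratio().to_csv(paths["logratio"], index=False)
    sims = pd.concat(
        [truth.true_similarity(p) for p in truth.config.periods], ignore_index=True
    )
    paths["similarity"] = outdir / "truth_similarity.csv"
    sims.to_csv(paths["similarity"], index=False)
    return paths
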