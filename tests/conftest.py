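import numpy as np
import pandas as pd
import pytest

from biotrend.records import GridSpec
from biotrend.simulate import SimConfig, generate_landscape, sample_records


@pytest.fixture
def grid():
    return GridSpec(cell_size=10.0, periods={"P1": (1950, 1969), "P2": (1970, 1989)})


@pytest.fixture
def tiny_records():
    """Nine records, two cells, two periods, three taxa."""
    return pd.DataFrame(
        {
            "taxon": ["A", "A", "B", "A", "C", "C", "B", "A", "A"],
            "x": [1.0, 2.0, 3.0, 11.0, 12.0, 1.5, 2.5, 12.0, 13.0],
            "y": [1.0, 2.0, 3.0, 1.0, 2.0, 1.5, 2.5, 1.0, 2.0],
            "year": [1955, 1956, 1957, 1958, 1959, 1975, 1976, 1977, 1978],
        }
    )


@pytest.fixture(scope="session")
def small_landscape():
    """A 5x5 landscape with known -20% change, sampled once."""
    cfg = SimConfig(
        grid_nx=5, grid_ny=5, n_species=120, extinction_fraction=0.2,
        effort_mean=600.0, seed=99,
    )
    truth = generate_landscape(cfg)
    records, effort = sample_records(truth)
    return cfg, truth, records, effort
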