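"""Parse raw occurrence files, lump aggregate taxa, and classify pollinator
dependency with taxonomic fallback.

Run: python examples/ingest_and_classify.py
"""

import tempfile
from pathlib import Path

import pandas as pd

from biotrend import (
    GridSpec,
    AssemblageTable,
    apply_aggregation,
    assign_grid_cells,
    classify_dependency,
    parse_records,
)

tmp = Path(tempfile.mkdtemp())
raw = tmp / "records.csv"
raw.write_text(
    "species,east_km,north_km,yr\n"
    "Bombus lucorum,12.3,45.1,1961\n"
    "Bombus terrestris,12.9,44.8,1963\n"
    "Bombus cryptarum,13.1,45.0,19xx\n"   # bad year: rejected
    "Poa annua,14.0,46.0,1978\n"
    "Poa trivialis,15.5,47.2,1981\n"
)

records, report = parse_records(
    raw, schema={"taxon": "species", "x": "east_km", "y": "north_km", "year": "yr"}
)
print(f"parsed {report.n_kept}/{report.n_read} rows; rejected: {report.reasons}")

# cryptic bumblebees indistinguishable across periods -> one aggregate taxon
lumped = apply_aggregation(
    records, {"Bombus lucorum": "Bombus lucorum agg.", "Bombus cryptarum": "Bombus lucorum agg."}
)
grid = GridSpec(cell_size=10.0)
gridded, dropped = assign_grid_cells(lumped, grid)
table = AssemblageTable.from_records(gridded, grid)
print(table.summary().to_string(index=False))

taxonomy = pd.DataFrame(
    {
        "taxon": ["Salvia pratensis", "Salvia verticillata", "Poa annua", "Festuca rubra"],
        "genus": ["Salvia", "Salvia", "Poa", "Festuca"],
        "family": ["Lamiaceae", "Lamiaceae", "Poaceae", "Poaceae"],
    }
)
traits = {"Salvia pratensis": "dependent", "Poa annua": "independent"}
classes = classify_dependency(traits, taxonomy)
print(classes.to_string(index=False))

# Salvia verticillata inherits "dependent" from its genus; Festuca rubra
# inherits "independent" from family Poaceae. A genus or family containing
# both dependent and independent species would yield "intermediate".
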