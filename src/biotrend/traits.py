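"""Pollinator-dependency classification with taxonomic fallback.

Plant taxa are classed as ``dependent``, ``intermediate`` or ``independent``
on flower visitors. Species with a direct trait entry keep it; unclassified
species inherit the consensus of classified congeners, then confamilials.
Mixed classes at the resolving level yield ``intermediate`` — a genus (or
family) containing both dependent and independent members gives no basis to
pick either extreme for its unknown species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["DependencyClass", "classify_dependency", "CLASSES"]

CLASSES = ("dependent", "intermediate", "independent")


@dataclass(frozen=True)
class DependencyClass:
    taxon: str
    dependency: str  # one of CLASSES, or "unclassified"
    provenance: str  # "species" | "genus" | "family" | "none"


def _consensus(classes: Iterable[str]) -> str | None:
    """Single shared class, 'intermediate' on conflict, None if empty."""
    uniq = set(classes)
    if not uniq:
        return None
    if len(uniq) == 1:
        return uniq.pop()
    return "intermediate"


def classify_dependency(
    trait_table: Mapping[str, str] | pd.DataFrame,
    taxonomy: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every taxon in ``taxonomy`` by species, genus, then family.

    Parameters
    ----------
    trait_table : mapping or DataFrame
        Species -> dependency class (columns ``taxon``, ``dependency`` if a
        DataFrame). Values must be in :data:`CLASSES`.
    taxonomy : DataFrame
        Columns ``taxon``, ``genus``, ``family`` covering all taxa to
        classify.

    Returns
    -------
    DataFrame with columns ``taxon``, ``dependency``, ``provenance``;
    taxa resolvable at no level come back ``unclassified`` / ``none``.
    """
    if isinstance(trait_table, pd.DataFrame):
        traits = dict(zip(trait_table["taxon"], trait_table["dependency"]))
    else:
        traits = dict(trait_table)
    bad = {v for v in traits.values()} - set(CLASSES)
    if bad:
        raise ValueError(f"unknown dependency class(es): {sorted(bad)}")

    tax = taxonomy.set_index("taxon")
    classified = {sp: cls for sp, cls in traits.items() if sp in tax.index}

    genus_classes: dict[str, list[str]] = {}
    family_classes: dict[str, list[str]] = {}
    for sp, cls in classified.items():
        genus_classes.setdefault(tax.loc[sp, "genus"], []).append(cls)
        family_classes.setdefault(tax.loc[sp, "family"], []).append(cls)

    rows = []
    for sp in taxonomy["taxon"]:
        if sp in traits:
            rows.append(DependencyClass(sp, traits[sp], "species"))
            continue
        genus = tax.loc[sp, "genus"]
        family = tax.loc[sp, "family"]
        cls = _consensus(genus_classes.get(genus, []))
        if cls is not None:
            rows.append(DependencyClass(sp, cls, "genus"))
            continue
        cls = _consensus(family_classes.get(family, []))
        if cls is not None:
            rows.append(DependencyClass(sp, cls, "family"))
        else:
            rows.append(DependencyClass(sp, "unclassified", "none"))
    return pd.DataFrame([r.__dict__ for r in rows])
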