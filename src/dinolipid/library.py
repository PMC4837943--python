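"""Shipped lipid species library and its text format.

The library is a tab-separated file with columns ``class``,
``total_carbons``, ``total_double_bonds`` and optional ``chains``
("a:b/c:d"), one species per row.  The packaged default reconstructs a
freshwater-dinoflagellate membrane-lipid inventory (9 MGDG, 13 DGDG,
10 TGDG, 9 SQDG, 29 DGCC, 19 PC, 3 PG, 3 PE); only the dominant species
are literature-attested, the remainder are plausible compositions over
the default chain alphabet.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .lipids import LIPID_CLASSES, LipidSpecies, parse_chain

__all__ = ["load_library", "default_library", "write_library"]


def _row_to_species(row: pd.Series) -> LipidSpecies:
    cls_name = str(row["class"]).upper()
    if cls_name not in LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {row['class']!r} in library")
    cls = LIPID_CLASSES[cls_name]
    chains = None
    raw = row.get("chains")
    if isinstance(raw, str) and raw.strip():
        a, b = (parse_chain(p) for p in raw.split("/"))
        chains = (a, b)
    return LipidSpecies(
        lipid_class=cls,
        total_carbons=int(row["total_carbons"]),
        total_double_bonds=int(row["total_double_bonds"]),
        chains=chains,
        regiochemistry_known=chains is not None and cls.regiochemistry_rule,
    )


def load_library(path: str | Path) -> list[LipidSpecies]:
    """Read a species library from delimited text."""
    df = pd.read_csv(path, sep="\t", dtype={"chains": "string"})
    required = {"class", "total_carbons", "total_double_bonds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library file lacks columns {sorted(missing)}")
    return [_row_to_species(row) for _, row in df.iterrows()]


def default_library() -> list[LipidSpecies]:
    """The packaged dinoflagellate membrane-lipid library."""
    ref = resources.files("dinolipid").joinpath("data/lipid_library.tsv")
    with resources.as_file(ref) as path:
        return load_library(path)


def write_library(species: Iterable[LipidSpecies], path: str | Path) -> None:
    rows = [
        {
            "class": s.lipid_class.name,
            "total_carbons": s.total_carbons,
            "total_double_bonds": s.total_double_bonds,
            "chains": s.chain_label or "",
        }
        for s in species
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
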