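"""Published reference measurements for ten freshwater dinoflagellates.

Two small tables shipped as package data:

* ``reference_markers.tsv`` — within-class percent relative areas of the
  eleven marker lipid species that separate the C18/C18 (group 1:
  *B. tenuissima*, *B. dodgei*, *P. aciculiferum*, *T. coronata*) and
  C20/C18 (group 2) regiochemistry clusters.  "n.d." (not detected)
  enters downstream statistics as 0.
* ``reference_galactolipid_split.tsv`` — per-taxon MGDG/DGDG percentages
  of the total galactolipid MGDG+DGDG signal and the published
  [DGDG]/[MGDG] ratio.  ``ratio_consistent`` flags taxa whose printed
  ratio agrees with their printed percentages at F = 1 (one taxon's does
  not, presumably through an instrument-specific internal-standard
  factor).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

GROUP1 = ["B_tenuissima", "B_dodgei", "P_aciculiferum", "T_coronata"]
GROUP2 = [
    "C_cornutum", "G_palustre", "J_applanata", "P_willei", "P_cinctum", "P_gatunense"
]

__all__ = ["GROUP1", "GROUP2", "marker_table", "galactolipid_split"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("dinolipid").joinpath(f"data/{name}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def marker_table(nd_as_zero: bool = True) -> pd.DataFrame:
    """Marker species × taxa percent areas (index: species label)."""
    df = _read("reference_markers.tsv").set_index("species")
    taxa = GROUP1 + GROUP2
    vals = df[taxa].replace("n.d.", np.nan).astype(float)
    if nd_as_zero:
        vals = vals.fillna(0.0)
    vals.insert(0, "group", df["group"])
    return vals


def galactolipid_split() -> pd.DataFrame:
    """Per-taxon MGDG/DGDG percentages and published [DGDG]/[MGDG] ratios."""
    return _read("reference_galactolipid_split.tsv").set_index("taxon")
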