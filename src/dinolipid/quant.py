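"""Class-wise relative quantification and unsaturation / chain-length indices.

Each lipid species is quantified relative to the summed area of all
species of the same class in the same sample, giving per-class
compositional profiles (fractions summing to 1).  From these the
unsaturation index UI = Σ(relative area × double bonds) and the average
chain length ACL = Σ(relative area × total acyl carbons) are computed
per class and sample, together with the MGDG/DGDG partition of the
galactolipid signal and the internal-standard-corrected
[DGDG]/[MGDG] ratio.

Species not detected in a sample are stored as 0 with a detection mask
and enter all downstream statistics as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lipids import parse_species_name

__all__ = [
    "FeatureTable",
    "QuantConfig",
    "relative_areas",
    "ui",
    "acl",
    "dgdg_mgdg_ratio",
    "class_index_report",
]


@dataclass
class QuantConfig:
    """Internal-standard normalisation for the galactolipid ratio.

    ``F`` is the response-factor ratio derived from co-analysed MGDG and
    DGDG standards (dimensionless); with no standards supplied F = 1.
    """

    F: float = 1.0
    response_factor_source: str = "none (F = 1)"

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("normalisation ratio F must be > 0")


class FeatureTable:
    """Samples × lipid species matrix of within-class relative areas.

    ``data`` holds fractions in [0, 1]; for every (sample, class) with at
    least one detected species the class rows sum to 1.  ``detected``
    marks observed cells; zeros outside the mask are "not detected".
    """

    def __init__(self, data: pd.DataFrame, detected: Optional[pd.DataFrame] = None):
        self.data = data.astype(float)
        self.detected = (
            detected.astype(bool) if detected is not None else self.data > 0
        )
        self.classes = pd.Series(
            {col: parse_species_name(col).lipid_class.name for col in data.columns}
        )
        self._validate()

    def _validate(self) -> None:
        vals = self.data.to_numpy()
        if (vals < -1e-12).any() or (vals > 1 + 1e-9).any():
            raise ValueError("relative areas must lie in [0, 1]")
        for cls, cols in self.class_columns.items():
            sums = self.data[cols].sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12))
            if bad.any():
                raise ValueError(
                    f"class {cls} does not sum to 1 in samples {list(sums.index[bad])}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def class_columns(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for col, cls in self.classes.items():
            out.setdefault(cls, []).append(col)
        return out

    def class_profile(self, sample: str, lipid_class: str) -> pd.Series:
        return self.data.loc[sample, self.class_columns[lipid_class]]

    # -- text round trip -------------------------------------------------
    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="sample")

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = "\t") -> "FeatureTable":
        df = pd.read_csv(path, sep=sep, index_col="sample")
        return cls(df)


def relative_areas(
    raw_areas: pd.DataFrame, class_map: Optional[Mapping[str, str]] = None
) -> FeatureTable:
    """Normalise raw areas to within-class fractions per sample.

    ``raw_areas`` is samples × species (columns labelled with the species
    grammar, e.g. "DGDG 36:9").  An all-zero class stays all-zero (the
    detection mask records the absence).  Negative areas are rejected.
    """
    neg = raw_areas < 0
    if neg.to_numpy().any():
        sample = neg.index[neg.any(axis=1)][0]
        col = neg.columns[neg.loc[sample]][0]
        raise ValueError(f"negative area at sample {sample!r}, species {col!r}")
    if class_map is None:
        class_map = {c: parse_species_name(c).lipid_class.name for c in raw_areas.columns}
    out = raw_areas.astype(float).copy()
    for cls in set(class_map.values()):
        cols = [c for c in raw_areas.columns if class_map[c] == cls]
        totals = out[cols].sum(axis=1)
        nz = totals > 0
        out.loc[nz, cols] = out.loc[nz, cols].div(totals[nz], axis=0)
    return FeatureTable(out, detected=raw_areas > 0)


def _weighted(profile: pd.Series, attr: str) -> float:
    total = float(profile.sum())
    if total == 0:
        return 0.0
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"class profile sums to {total}, expected 1 (or 0 if absent)")
    weights = np.array(
        [getattr(parse_species_name(lbl), attr) for lbl in profile.index], dtype=float
    )
    return float(np.dot(profile.to_numpy(), weights))


def ui(profile: pd.Series) -> float:
    """Unsaturation index of one sample's relative-area profile of a class."""
    return _weighted(profile, "total_double_bonds")


def acl(profile: pd.Series) -> float:
    """Average (area-weighted total) acyl chain length of a class profile."""
    return _weighted(profile, "total_carbons")


def dgdg_mgdg_ratio(
    mgdg_total_area: float, dgdg_total_area: float, config: QuantConfig | None = None
) -> float:
    """[DGDG]/[MGDG] area ratio with internal-standard correction F.

    Values > 1 indicate DGDG-dominant galactolipid signal.  Undefined for
    zero MGDG signal.
    """
    config = config or QuantConfig()
    if mgdg_total_area <= 0 or dgdg_total_area <= 0:
        raise ZeroDivisionError(
            "MGDG and DGDG totals must both be positive for the ratio"
        )
    return (dgdg_total_area / mgdg_total_area) * config.F


def class_index_report(
    table: FeatureTable,
    raw_areas: Optional[pd.DataFrame] = None,
    config: QuantConfig | None = None,
) -> pd.DataFrame:
    """Per-sample lipid parameters: UI and ACL per class, galactolipid split.

    When ``raw_areas`` is given, MGDG%/DGDG% and the [DGDG]/[MGDG] ratio
    are computed from summed raw class areas; otherwise these columns are
    omitted (within-class fractions carry no between-class information).
    UI/ACL columns report one decimal less aggressively than the
    underlying floats — rounding is left to the presentation layer.
    """
    config = config or QuantConfig()
    rows = []
    for sample in table.samples:
        row: dict[str, float | str] = {"sample": sample}
        for cls in table.class_columns:
            prof = table.class_profile(sample, cls)
            row[f"UI {cls}"] = ui(prof)
            row[f"ACL {cls}"] = acl(prof)
        if raw_areas is not None:
            cols_m = [c for c in raw_areas.columns if c.startswith("MGDG ")]
            cols_d = [c for c in raw_areas.columns if c.startswith("DGDG ")]
            m = float(raw_areas.loc[sample, cols_m].sum())
            d = float(raw_areas.loc[sample, cols_d].sum())
            if m + d > 0:
                row["MGDG (%)"] = 100.0 * m / (m + d)
                row["DGDG (%)"] = 100.0 * d / (m + d)
            if m > 0 and d > 0:
                row["[DGDG]/[MGDG]"] = dgdg_mgdg_ratio(m, d, config)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
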