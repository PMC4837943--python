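"""Delimited-text readers/writers for the pipeline's interchange formats.

All formats are plain TSV: MS1 peak lists (sample, polarity, rt, m/z,
area), MS2 spectra (spectrum id, precursor m/z, polarity, fragment m/z,
intensity), feature tables (samples × species labels) and distance
matrices.  mzML ingestion is deliberately not part of the core surface.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import Ms2Spectrum, PeakList

__all__ = [
    "read_peaklists",
    "write_peaklists",
    "read_ms2",
    "write_ms2",
]


def write_peaklists(peaklists: Sequence[PeakList], path: str | Path) -> None:
    rows = [
        {"sample": pl.sample_id, "polarity": pl.polarity, "rt": rt, "mz": mz, "area": area}
        for pl in peaklists
        for rt, mz, area in pl.peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peaklists(path: str | Path) -> list[PeakList]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "polarity", "rt", "mz", "area"}
    if missing := required - set(df.columns):
        raise ValueError(f"peak-list file lacks columns {sorted(missing)}")
    out = []
    for (sample, pol), grp in df.groupby(["sample", "polarity"], sort=True):
        peaks = list(zip(grp["rt"], grp["mz"], grp["area"]))
        out.append(PeakList(str(sample), str(pol), peaks))
    return out


def write_ms2(spectra: Sequence[Ms2Spectrum], path: str | Path) -> None:
    rows = [
        {
            "spectrum": i,
            "precursor_mz": s.precursor_mz,
            "polarity": s.polarity,
            "fragment_mz": fmz,
            "intensity": inten,
        }
        for i, s in enumerate(spectra)
        for fmz, inten in s.fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ms2(path: str | Path) -> list[Ms2Spectrum]:
    df = pd.read_csv(path, sep="\t")
    required = {"spectrum", "precursor_mz", "polarity", "fragment_mz", "intensity"}
    if missing := required - set(df.columns):
        raise ValueError(f"MS2 file lacks columns {sorted(missing)}")
    out = []
    for _, grp in df.groupby("spectrum", sort=True):
        out.append(
            Ms2Spectrum(
                float(grp["precursor_mz"].iloc[0]),
                str(grp["polarity"].iloc[0]),
                list(zip(grp["fragment_mz"], grp["intensity"])),
            )
        )
    return out
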