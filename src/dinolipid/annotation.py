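"""MS1 species matching and MS2 chain / regiochemistry assignment.

MS1 peaks are matched against theoretical adduct m/z of a species library
within a mass tolerance (unit-resolution ion trap: default ±0.3 Da).
MS2 spectra are interpreted as neutral losses of the two acyl chains,
each lost either as the free carboxylic acid or as the ketene
(acid − H2O).  For galactolipids the loss of the *sn*-1 chain gives the
more intense fragment, which resolves the regiochemistry; for the
betaine lipid DGCC and for PC the fragmentation carries no positional
information and the chain pair is reported unordered.

Retention time is carried through but never used for matching
(chromatography is outside this package's scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .lipids import (
    ADDUCTS,
    DEFAULT_CHAIN_ALPHABET,
    AcylChain,
    Adduct,
    LipidSpecies,
    adduct_mz,
    chain_mass,
    enumerate_chain_pairs,
    species_mass,
)

__all__ = [
    "PeakList",
    "Ms2Spectrum",
    "ChainEvidence",
    "AnnotationResult",
    "AnnotationConfig",
    "match_ms1",
    "assign_chains_ms2",
    "annotate_run",
]

Polarity = Literal["positive", "negative"]

#: relative intensity difference below which the sn-1 rule is a tie
TIE_RELATIVE = 0.01


@dataclass
class PeakList:
    """MS1 peaks of one sample in one ionisation mode."""

    sample_id: str
    polarity: Polarity
    peaks: list[tuple[float, float, float]]  # (rt_min, mz, area)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        for rt, mz, area in self.peaks:
            if area < 0:
                raise ValueError(f"negative area {area} at m/z {mz}")


@dataclass
class Ms2Spectrum:
    """A product-ion spectrum; fragments kept sorted by m/z."""

    precursor_mz: float
    polarity: Polarity
    fragments: list[tuple[float, float]]  # (mz, intensity)

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("MS2 spectrum needs at least one fragment")
        if any(i < 0 for _, i in self.fragments):
            raise ValueError("negative fragment intensity")
        self.fragments = sorted(self.fragments)


@dataclass(frozen=True)
class ChainEvidence:
    chain: AcylChain
    fragment_mz: float
    intensity: float
    form: Literal["acid", "ketene"]
    error: float  # observed − predicted, Da


@dataclass
class AnnotationResult:
    """One candidate species for one MS1 peak, possibly chain-resolved."""

    species: LipidSpecies
    adduct: Adduct
    observed_mz: float
    mz_error: float  # observed − theoretical, Da
    area: float
    sample_id: str = ""
    peak_index: int = -1
    chain_evidence: tuple[ChainEvidence, ...] = ()
    regiochemistry: Literal["assigned", "unordered", "unresolved"] = "unresolved"


@dataclass
class AnnotationConfig:
    tolerance: float = 0.3
    allowed_chains: frozenset[AcylChain] = DEFAULT_CHAIN_ALPHABET

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("mass tolerance must be positive")


def _candidate_mz_table(
    library: Sequence[LipidSpecies], polarity: Polarity
) -> tuple[np.ndarray, list[tuple[LipidSpecies, Adduct]]]:
    pairs: list[tuple[LipidSpecies, Adduct]] = []
    mzs: list[float] = []
    for sp in library:
        for label in sp.lipid_class.preferred_adducts.get(polarity, ()):
            ad = ADDUCTS[label]
            pairs.append((sp, ad))
            mzs.append(adduct_mz(species_mass(sp), ad))
    return np.asarray(mzs), pairs


def match_ms1(
    peaklist: PeakList,
    library: Sequence[LipidSpecies],
    tolerance: float = 0.3,
) -> list[AnnotationResult]:
    """Match every peak against every (species, preferred adduct) m/z.

    All candidates within ``tolerance`` are returned; candidates for the
    same peak are ranked by absolute m/z error.  Output order depends
    only on (peak m/z, error), not on input peak order.
    """
    if tolerance <= 0:
        raise ValueError("mass tolerance must be positive")
    if not library:
        raise ValueError("species library is empty")
    theo, pairs = _candidate_mz_table(library, peaklist.polarity)
    results: list[AnnotationResult] = []
    order = sorted(range(len(peaklist.peaks)), key=lambda i: peaklist.peaks[i][1])
    for idx in order:
        rt, mz, area = peaklist.peaks[idx]
        errs = mz - theo
        hits = np.flatnonzero(np.abs(errs) <= tolerance)
        for j in hits[np.argsort(np.abs(errs[hits]), kind="stable")]:
            sp, ad = pairs[j]
            results.append(
                AnnotationResult(
                    species=sp,
                    adduct=ad,
                    observed_mz=mz,
                    mz_error=float(errs[j]),
                    area=area,
                    sample_id=peaklist.sample_id,
                    peak_index=idx,
                )
            )
    return results


def _predicted_losses(
    precursor: float, chain: AcylChain, offsets: tuple[float, float]
) -> dict[str, float]:
    return {
        "acid": precursor - (chain_mass(chain, "acid") + offsets[0]),
        "ketene": precursor - (chain_mass(chain, "ketene") + offsets[1]),
    }


def _best_fragment(
    spectrum: Ms2Spectrum, predicted: float, tolerance: float
) -> Optional[tuple[float, float, float]]:
    """(mz, intensity, error) of the closest fragment within tolerance."""
    best = None
    for fmz, inten in spectrum.fragments:
        err = fmz - predicted
        if abs(err) <= tolerance and (best is None or abs(err) < abs(best[2])):
            best = (fmz, inten, err)
    return best


def _match_chain(
    spectrum: Ms2Spectrum,
    precursor: float,
    chain: AcylChain,
    offsets: tuple[float, float],
    tolerance: float,
) -> Optional[ChainEvidence]:
    best: Optional[ChainEvidence] = None
    for form, pred in _predicted_losses(precursor, chain, offsets).items():
        hit = _best_fragment(spectrum, pred, tolerance)
        if hit is not None and (best is None or abs(hit[2]) < abs(best.error)):
            best = ChainEvidence(chain, hit[0], hit[1], form, hit[2])  # type: ignore[arg-type]
    return best


def assign_chains_ms2(
    candidate: AnnotationResult,
    spectrum: Ms2Spectrum,
    allowed: Iterable[AcylChain] = DEFAULT_CHAIN_ALPHABET,
    tolerance: float = 0.3,
) -> AnnotationResult:
    """Resolve acyl chains (and, for galactolipids, sn-positions) from MS2.

    Every chain pair compatible with the candidate's sum composition is
    scored by the summed |error| of its two matched neutral losses; the
    best doubly-matched pair wins.  For galactolipid classes the chain
    whose loss fragment is more intense is placed at *sn*-1; an intensity
    tie (within 1% relative) leaves the order unresolved.  DGCC/PC pairs
    are always reported unordered.
    """
    sp = candidate.species
    if abs(spectrum.precursor_mz - (candidate.observed_mz)) > 2 * tolerance:
        raise ValueError(
            f"precursor {spectrum.precursor_mz} does not match candidate "
            f"m/z {candidate.observed_mz}"
        )
    offsets = sp.lipid_class.ms2_loss_offsets
    precursor = spectrum.precursor_mz
    best_pair: Optional[tuple[ChainEvidence, ChainEvidence]] = None
    best_err = np.inf
    best_single: Optional[ChainEvidence] = None
    for pair in enumerate_chain_pairs(sp.total_carbons, sp.total_double_bonds, allowed):
        chains = sorted(pair) if len(pair) == 2 else [next(iter(pair))] * 2
        ev = [_match_chain(spectrum, precursor, c, offsets, tolerance) for c in chains]
        for e in ev:
            if e is not None and (
                best_single is None or abs(e.error) < abs(best_single.error)
            ):
                best_single = e
        if all(e is not None for e in ev):
            err = sum(abs(e.error) for e in ev)  # type: ignore[union-attr]
            if err < best_err:
                best_err = err
                best_pair = tuple(ev)  # type: ignore[assignment]

    if best_pair is None:
        return replace(
            candidate,
            chain_evidence=(best_single,) if best_single else (),
            regiochemistry="unresolved",
        )

    e1, e2 = best_pair
    cls = sp.lipid_class
    if cls.regiochemistry_rule and e1.chain != e2.chain:
        hi, lo = (e1, e2) if e1.intensity >= e2.intensity else (e2, e1)
        if hi.intensity > 0 and (hi.intensity - lo.intensity) > TIE_RELATIVE * hi.intensity:
            species = replace(
                sp, chains=(hi.chain, lo.chain), regiochemistry_known=True
            )
            return replace(
                candidate,
                species=species,
                chain_evidence=(hi, lo),
                regiochemistry="assigned",
            )
        verdict = "unresolved"  # intensity tie: the rule is an inequality
    elif cls.regiochemistry_rule:
        # identical chains: positional assignment is unambiguous by symmetry
        species = replace(sp, chains=(e1.chain, e2.chain), regiochemistry_known=True)
        return replace(
            candidate, species=species, chain_evidence=(e1, e2), regiochemistry="assigned"
        )
    else:
        verdict = "unordered"
    chains = tuple(sorted((e1.chain, e2.chain)))
    species = replace(sp, chains=chains, regiochemistry_known=False)
    return replace(
        candidate, species=species, chain_evidence=(e1, e2), regiochemistry=verdict
    )


def _ms2_for(
    candidate: AnnotationResult, ms2: Sequence[Ms2Spectrum], polarity: Polarity, tol: float
) -> Optional[Ms2Spectrum]:
    best, best_d = None, np.inf
    for spec in ms2:
        if spec.polarity != polarity:
            continue
        d = abs(spec.precursor_mz - candidate.observed_mz)
        if d <= tol and d < best_d:
            best, best_d = spec, d
    return best


def annotate_run(
    peaklists: Sequence[PeakList],
    ms2: Sequence[Ms2Spectrum],
    library: Sequence[LipidSpecies],
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Annotate a full acquisition: one row per species per sample.

    Each peak keeps its rank-1 candidate.  Areas are summed over a
    species' peaks in its class's quantification polarity; species seen
    only in the other polarity are reported with ``quantified=False``.
    """
    config = config or AnnotationConfig()
    if not peaklists:
        raise ValueError("at least one peak list (one polarity) is required")
    rows: dict[tuple[str, str], dict] = {}
    for pl in peaklists:
        cands = match_ms1(pl, library, config.tolerance)
        seen_peaks: set[int] = set()
        for cand in cands:  # already ranked per peak; keep first per peak
            if cand.peak_index in seen_peaks:
                continue
            seen_peaks.add(cand.peak_index)
            spec2 = _ms2_for(cand, ms2, pl.polarity, config.tolerance)
            if spec2 is not None:
                cand = assign_chains_ms2(
                    cand, spec2, config.allowed_chains, config.tolerance
                )
            sp = cand.species
            in_quant = pl.polarity == sp.lipid_class.quant_polarity
            key = (pl.sample_id, sp.label)
            row = rows.setdefault(
                key,
                {
                    "sample": pl.sample_id,
                    "species": sp.label,
                    "lipid_class": sp.lipid_class.name,
                    "area": 0.0,
                    "quantified": False,
                    "chains": None,
                    "regiochemistry": "unresolved",
                    "mz_error": cand.mz_error,
                },
            )
            if in_quant:
                row["area"] += cand.area
                row["quantified"] = True
            if cand.regiochemistry in ("assigned", "unordered") and row["chains"] is None:
                row["chains"] = sp.chain_label
                row["regiochemistry"] = cand.regiochemistry
    df = pd.DataFrame(rows.values())
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "sample", "species", "lipid_class", "area",
                "quantified", "chains", "regiochemistry", "mz_error",
            ]
        )
    return df.sort_values(["sample", "lipid_class", "species"]).reset_index(drop=True)
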