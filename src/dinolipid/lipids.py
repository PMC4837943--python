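"""Domain model for intact glycerolipid species and their monoisotopic masses.

The lipid classes covered are the thylakoid galactolipids (MGDG, DGDG,
TGDG), the sulfolipid SQDG, the betaine lipid DGCC and the phospholipids
PC, PE and PG — i.e. the membrane-lipid inventory of freshwater
dinoflagellates as profiled by reversed-phase ESI ion-trap MS.  Every
species is a diacylglycerol: a glycerol backbone esterified with two acyl
chains at *sn*-1/*sn*-2 and carrying the class head group at *sn*-3.

Masses are monoisotopic throughout (ion-trap annotation convention) and
are computed from elemental compositions via :mod:`pyteomics.mass`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "AcylChain",
    "Adduct",
    "LipidClass",
    "LipidSpecies",
    "ADDUCTS",
    "LIPID_CLASSES",
    "DEFAULT_CHAIN_ALPHABET",
    "parse_chain",
    "parse_species_name",
    "chain_mass",
    "species_mass",
    "adduct_mz",
    "enumerate_chain_pairs",
]

_WATER = _pmass.Composition(formula="H2O")
_GLYCEROL = _pmass.Composition(formula="C3H8O3")
_ELECTRON = 0.00054857990907

Polarity = Literal["positive", "negative"]


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty acyl chain, ``carbons:double_bonds`` (e.g. 18:5).

    The free-acid elemental composition is C_n H_(2n-2d) O_2.
    """

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError(
                f"double bonds must lie in [0, C/2] for {self.carbons}:{self.double_bonds}"
            )

    @property
    def acid_composition(self) -> _pmass.Composition:
        return _pmass.Composition(
            C=self.carbons, H=2 * self.carbons - 2 * self.double_bonds, O=2
        )

    def __str__(self) -> str:  # "18:5"
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class Adduct:
    """An ESI adduct for singly charged ions."""

    label: str
    mass_shift: float
    charge: int

    def mz(self, neutral_mass: float) -> float:
        return (neutral_mass + self.mass_shift) / abs(self.charge)


_PROTON = 1.00782503207 - _ELECTRON
_NA = 22.9897692809 - _ELECTRON
_NH4 = 14.0030740048 + 4 * 1.00782503207 - _ELECTRON
_ACETATE = 2 * 12.0 + 3 * 1.00782503207 + 2 * 15.9949146196 + _ELECTRON

ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", _PROTON, +1),
    "[M+Na]+": Adduct("[M+Na]+", _NA, +1),
    "[M+NH4]+": Adduct("[M+NH4]+", _NH4, +1),
    "[M-H]-": Adduct("[M-H]-", -_PROTON, -1),
    "[M+CH3COO]-": Adduct("[M+CH3COO]-", _ACETATE, -1),
}


@dataclass(frozen=True)
class LipidClass:
    """A glycerolipid class: head-group chemistry plus acquisition rules.

    ``residue`` is the elemental composition added to the plain
    diacylglycerol by head-group condensation (net of the water lost in
    each glycosidic / phosphodiester / ether bond).  ``quant_polarity``
    is the ionisation mode whose MS1 areas are used for relative
    quantification.  ``ms2_loss_offsets`` are per-class calibratable mass
    offsets added to the predicted acid / ketene neutral losses (default
    0 = plain acid / ketene arithmetic).
    """

    name: str
    residue: _pmass.Composition
    quant_polarity: Polarity
    preferred_adducts: dict[Polarity, tuple[str, ...]]
    regiochemistry_rule: bool = False
    ms2_loss_offsets: tuple[float, float] = (0.0, 0.0)  # (acid, ketene)
    n_chains: int = 2


def _cls(
    name: str,
    residue_formula: str,
    quant_polarity: Polarity,
    pos: tuple[str, ...],
    neg: tuple[str, ...],
    regio: bool,
) -> LipidClass:
    return LipidClass(
        name=name,
        residue=_pmass.Composition(formula=residue_formula),
        quant_polarity=quant_polarity,
        preferred_adducts={"positive": pos, "negative": neg},
        regiochemistry_rule=regio,
    )


#: Class registry.  Galactolipids (MGDG/DGDG/TGDG), DGCC and PC are
#: quantified in positive mode; PE, PG and SQDG in negative mode.  The
#: sn-1-more-intense MS2 rule applies to the galactolipids only.
LIPID_CLASSES: dict[str, LipidClass] = {
    c.name: c
    for c in [
        # anhydro-hexose residues for the galactolipid series; sodiated
        # ions dominate in ammonium-acetate positive mode
        _cls("MGDG", "C6H10O5", "positive", ("[M+Na]+",), (), True),
        _cls("DGDG", "C12H20O10", "positive", ("[M+Na]+",), (), True),
        _cls("TGDG", "C18H30O15", "positive", ("[M+Na]+",), (), True),
        # sulfoquinovose; the sulfonate ionises essentially only negative
        _cls("SQDG", "C6H10O7S", "negative", (), ("[M-H]-",), False),
        # carboxy-(hydroxymethyl)-choline, ether-linked
        _cls("DGCC", "C6H11NO3", "positive", ("[M+H]+",), (), False),
        _cls("PC", "C5H12NO3P", "positive", ("[M+H]+",), ("[M+CH3COO]-",), False),
        _cls("PE", "C2H6NO3P", "negative", ("[M+H]+",), ("[M-H]-",), False),
        _cls("PG", "C3H7O5P", "negative", ("[M+H]+",), ("[M-H]-",), False),
    ]
}

#: Acyl chains observed in freshwater dinoflagellate glycerolipids.
DEFAULT_CHAIN_ALPHABET: frozenset[AcylChain] = frozenset(
    AcylChain(c, d)
    for c, d in [
        (14, 0), (16, 0), (16, 1), (18, 0), (18, 1),
        (18, 3), (18, 4), (18, 5), (20, 5), (22, 6),
    ]
)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at sum-composition or chain-resolved level.

    ``chains`` may be ``None`` (sum composition only), an unordered pair
    (chains known, positions not) or an ordered (*sn*-1, *sn*-2) pair.
    ``regiochemistry_known`` is true only when the order is resolved,
    which the fragment-intensity rule permits for galactolipids alone.
    """

    lipid_class: LipidClass
    total_carbons: int
    total_double_bonds: int
    chains: Optional[tuple[AcylChain, AcylChain]] = None
    regiochemistry_known: bool = False

    def __post_init__(self) -> None:
        if self.chains is not None:
            a, b = self.chains
            if a.carbons + b.carbons != self.total_carbons:
                raise ValueError(
                    f"chain carbons {a}+{b} != total {self.total_carbons}"
                )
            if a.double_bonds + b.double_bonds != self.total_double_bonds:
                raise ValueError(
                    f"chain double bonds {a}+{b} != total {self.total_double_bonds}"
                )
            if not self.regiochemistry_known and not self.lipid_class.regiochemistry_rule:
                # store unordered pairs canonically (sorted) for DGCC/PC etc.
                object.__setattr__(self, "chains", tuple(sorted(self.chains)))
        if self.regiochemistry_known and not self.lipid_class.regiochemistry_rule:
            raise ValueError(
                f"regiochemistry cannot be assigned for class {self.lipid_class.name}"
            )

    @property
    def label(self) -> str:
        return f"{self.lipid_class.name} {self.total_carbons}:{self.total_double_bonds}"

    @property
    def chain_label(self) -> Optional[str]:
        if self.chains is None:
            return None
        return f"{self.chains[0]}/{self.chains[1]}"

    def __str__(self) -> str:
        if self.chains is None:
            return self.label
        return f"{self.label} ({self.chain_label})"


_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")
_NAME_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z]+)\s+(?P<a>\d+):(?P<b>\d+)"
    r"(?:/(?P<c>\d+):(?P<d>\d+))?"
    r"(?:\s*\(\s*(?P<e>\d+):(?P<f>\d+)\s*/\s*(?P<g>\d+):(?P<h>\d+)\s*\))?\s*$"
)


def parse_chain(text: str) -> AcylChain:
    """Parse ``"18:5"`` into an :class:`AcylChain`."""
    m = _CHAIN_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse acyl chain {text!r}")
    return AcylChain(int(m.group(1)), int(m.group(2)))


def parse_species_name(text: str) -> LipidSpecies:
    """Parse a species label into a :class:`LipidSpecies`.

    Accepted grammars: ``"DGDG 36:9"`` (sum composition),
    ``"MGDG 18:5/18:4"`` (chain-resolved; totals derived) and
    ``"DGCC 38:6 (16:0/22:6)"`` (both; totals must agree with the chains).
    Class names are recognised case-insensitively.
    """
    m = _NAME_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse species label {text!r}")
    cls_name = m.group("cls").upper()
    if cls_name not in LIPID_CLASSES:
        raise ValueError(f"unknown lipid class {m.group('cls')!r}")
    cls = LIPID_CLASSES[cls_name]

    chains: Optional[tuple[AcylChain, AcylChain]] = None
    if m.group("e") is not None:
        # "<CLASS> C:D (c1:d1/c2:d2)" — first pair is the stated sum
        chains = (
            AcylChain(int(m.group("e")), int(m.group("f"))),
            AcylChain(int(m.group("g")), int(m.group("h"))),
        )
        total_c, total_d = int(m.group("a")), int(m.group("b"))
        if (
            chains[0].carbons + chains[1].carbons != total_c
            or chains[0].double_bonds + chains[1].double_bonds != total_d
        ):
            raise ValueError(
                f"stated sum composition {total_c}:{total_d} inconsistent with "
                f"chains {chains[0]}/{chains[1]} in {text!r}"
            )
    elif m.group("c") is not None:
        # "<CLASS> c1:d1/c2:d2" — chain-resolved
        chains = (
            AcylChain(int(m.group("a")), int(m.group("b"))),
            AcylChain(int(m.group("c")), int(m.group("d"))),
        )
        total_c = chains[0].carbons + chains[1].carbons
        total_d = chains[0].double_bonds + chains[1].double_bonds
    else:
        total_c, total_d = int(m.group("a")), int(m.group("b"))

    return LipidSpecies(
        lipid_class=cls,
        total_carbons=total_c,
        total_double_bonds=total_d,
        chains=chains,
        regiochemistry_known=chains is not None and cls.regiochemistry_rule,
    )


def chain_mass(chain: AcylChain, form: Literal["acid", "ketene"] = "acid") -> float:
    """Monoisotopic mass (Da) of a chain as free fatty acid or ketene.

    The ketene (RCH=C=O) is the acid minus one water — the two neutral
    losses observed for ester-linked chains in MS/MS.
    """
    comp = chain.acid_composition
    if form == "ketene":
        comp = comp - _WATER
    elif form != "acid":
        raise ValueError(f"form must be 'acid' or 'ketene', got {form!r}")
    return _pmass.calculate_mass(composition=comp)


def species_composition(species: LipidSpecies) -> _pmass.Composition:
    """Elemental composition of the neutral species.

    glycerol + head-group residue + both acyl chains as free acids minus
    two esterification waters.  Depends only on the sum composition, so
    chain order (or absence) never changes the result; the sum
    composition is expressed through a single virtual saturated-equivalent
    pair of chains.
    """
    c, d = species.total_carbons, species.total_double_bonds
    acyl = _pmass.Composition(C=c, H=2 * c - 2 * d, O=4)  # two acids pooled
    return _GLYCEROL + species.lipid_class.residue + acyl - _WATER - _WATER


def species_mass(species: LipidSpecies) -> float:
    """Neutral monoisotopic mass (Da) of a species from its sum composition."""
    return _pmass.calculate_mass(composition=species_composition(species))


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of a singly charged adduct of the given neutral mass."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unsupported adduct {adduct!r}") from None
    return adduct.mz(neutral_mass)


def enumerate_chain_pairs(
    total_carbons: int,
    total_double_bonds: int,
    allowed: Sequence[AcylChain] | frozenset[AcylChain] = DEFAULT_CHAIN_ALPHABET,
) -> set[frozenset[AcylChain]]:
    """All unordered chain pairs from ``allowed`` matching a sum composition.

    A pair may repeat a chain (e.g. 36:10 = 18:5/18:5).  The empty set is
    a valid result for impossible decompositions.
    """
    allowed = sorted(set(allowed))
    if not allowed:
        raise ValueError("allowed chain alphabet is empty")
    out: set[frozenset[AcylChain]] = set()
    for a, b in itertools.combinations_with_replacement(allowed, 2):
        if (
            a.carbons + b.carbons == total_carbons
            and a.double_bonds + b.double_bonds == total_double_bonds
        ):
            out.add(frozenset((a, b)))
    return out
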