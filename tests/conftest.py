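import numpy as np
import pandas as pd
import pytest

from dinolipid.library import default_library
from dinolipid.multivariate import ParetoScaler
from dinolipid.synthetic import SyntheticDesign, gen_feature_table

#: one fixed seed for every stochastic check in the suite
SUITE_SEED = 20160524 % (2**31)

#: monoisotopic atomic masses, coded independently of the package
ATOMIC = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: head-group residues re-derived from the textbook structures
#: (elements added to the diacylglycerol by head-group condensation)
ORACLE_RESIDUES = {
    "MGDG": {"C": 6, "H": 10, "O": 5},
    "DGDG": {"C": 12, "H": 20, "O": 10},
    "TGDG": {"C": 18, "H": 30, "O": 15},
    "SQDG": {"C": 6, "H": 10, "O": 7, "S": 1},
    "DGCC": {"C": 6, "H": 11, "N": 1, "O": 3},
    "PC": {"C": 5, "H": 12, "N": 1, "O": 3, "P": 1},
    "PE": {"C": 2, "H": 6, "N": 1, "O": 3, "P": 1},
    "PG": {"C": 3, "H": 7, "O": 5, "P": 1},
}


def oracle_species_mass(cls_name: str, carbons: int, double_bonds: int) -> float:
    """Independent mass oracle: glycerol + residue + acyls − 2 H2O."""
    counts = dict(ORACLE_RESIDUES[cls_name])
    for el, k in (("C", 3), ("H", 8), ("O", 3)):  # glycerol
        counts[el] = counts.get(el, 0) + k
    counts["C"] += carbons
    counts["H"] += 2 * carbons - 2 * double_bonds
    counts["O"] = counts.get("O", 0) + 4
    counts["H"] -= 4  # two esterification waters
    counts["O"] -= 2
    return sum(ATOMIC[el] * k for el, k in counts.items())


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def two_group_table():
    """Default synthetic two-group study: table, group labels."""
    return gen_feature_table(SyntheticDesign(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def preprocessed(two_group_table):
    table, groups = two_group_table
    scaler = ParetoScaler().fit(table.data)
    return scaler.transform(table.data), groups, scaler, table
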