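"""Pinned physical constants and composition tables.

All mass arithmetic in the package goes through the tables in this module so
that results are reproducible bit-for-bit across environments.  Monoisotopic
masses are CODATA/AME values; average masses are IUPAC 2005 standard atomic
weights (the convention used by common peptide mass calculators).
"""

from __future__ import annotations

# Monoisotopic atomic masses, Da (CODATA / AME2020).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

# Average atomic masses, Da (IUPAC 2005 standard atomic weights).
AVERAGE_MASS: dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.065,
    "Na": 22.98977,
}

# Cation masses for adduct ions (include the electron by the stated
# convention: these are the masses of H+ and Na+ as charged species).
CATION_MASS: dict[str, float] = {
    "proton": 1.00728,
    "sodium": 22.98922,
}

# Mass added per backbone amide on H -> D substitution, Da.
DEUTERIUM_INCREMENT = 1.00628

# Amino-acid residue (monomer) elemental compositions.  "B" is
# 2-aminobutyric acid (Abu), the isosteric thiol-free cysteine replacement
# used in the synthetic CD160 fragments.
RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "B": {"C": 4, "H": 7, "N": 1, "O": 1},  # Abu
}

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

WATER = {"H": 2, "O": 1}

# Terminal modifications, as composition deltas relative to the free form.
ACETYL_DELTA = {"C": 2, "H": 2, "O": 1}          # N-terminal acetylation
AMIDE_DELTA = {"O": -1, "N": 1, "H": 1}          # C-terminal amidation

# Linker moieties for ELISA-construct bookkeeping (already condensed, i.e.
# the composition added to the peptide as attached).
MOIETY_FORMULA: dict[str, dict[str, int]] = {
    "gly5": {"C": 10, "H": 15, "N": 5, "O": 5},           # penta-glycine
    "biotin": {"C": 10, "H": 14, "N": 2, "O": 2, "S": 1},  # biotinyl
}

# Van der Waals radii by element, A (Bondi-style set used for SASA).
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
VDW_DEFAULT = 1.70

SASA_PROBE_RADIUS = 1.4   # A, water probe
SASA_N_POINTS = 960       # fixed quadrature density for reproducibility

# Theoretical maximum accessible surface area per residue type, A^2
# (Tien et al. 2013, theoretical values); used to normalize to relative SASA.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
MAX_ASA_DEFAULT = 197.0

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "ABU": "B",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def mass_of_formula(formula: dict[str, int], table: dict[str, float]) -> float:
    """Sum a composition map against an atomic-mass table."""
    return sum(count * table[el] for el, count in formula.items())
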