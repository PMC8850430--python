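"""Physical constants for peptide mass chemistry.

Monoisotopic element masses and natural isotopic abundances follow the
IUPAC/CODATA recommended values. Residue formulas are the standard
dehydrated (in-chain) compositions of the 20 canonical amino acids; the
monoisotopic residue masses used throughout the package are derived from
these formulas and the element masses below, so that mass arithmetic and
elemental-composition arithmetic can never disagree.
"""

from __future__ import annotations

PROTON_MASS = 1.007276
WATER_MASS = 18.010565

# Spacing of one extra neutron in a C/H/N/O/S molecule, dominated by 13C.
C13_DELTA = 1.003355

# Gln/Asn -> Glu/Asp: -H -N +O
DEAMIDATION_DELTA = 0.984016

# (mass Da, abundance) per isotope, ordered by increasing nominal mass.
# Only C/H/N/O/S are supported: peptides contain nothing else.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "N": ((14.0030740048, 0.99636), (15.0001088982, 0.00364)),
    "O": ((15.9949146196, 0.99757), (16.9991317012, 0.00038), (17.9991596129, 0.00205)),
    "S": ((31.97207100, 0.9499), (32.97145876, 0.0075), (33.96786690, 0.0425), (35.96708076, 0.0001)),
}

MONO_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

# In-chain residue compositions (peptide bond formed, one water removed).
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
}

CANONICAL_RESIDUES = frozenset(RESIDUE_FORMULA)

WATER_FORMULA: dict[str, int] = {"H": 2, "O": 1}


def formula_mono_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental formula (signed counts allowed)."""
    return sum(MONO_MASS[el] * n for el, n in formula.items())


RESIDUE_MASS: dict[str, float] = {aa: formula_mono_mass(f) for aa, f in RESIDUE_FORMULA.items()}
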