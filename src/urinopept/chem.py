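"""Peptide and modification chemistry.

This module is the mass backbone of the pipeline: it parses search-engine
style modified sequences (``"Q(-17.03)TFPHQ..."``), computes elemental
compositions and monoisotopic masses, converts mass to m/z, and builds
theoretical isotope envelopes by convolution of per-element natural
abundance tables.

Coordinate convention: modification positions are 1-based residue indices
("N-term" modifications such as pyroglutamate live at position 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

from ._constants import (
    C13_DELTA,
    CANONICAL_RESIDUES,
    DEAMIDATION_DELTA,
    ISOTOPES,
    PROTON_MASS,
    RESIDUE_FORMULA,
    RESIDUE_MASS,
    WATER_FORMULA,
    WATER_MASS,
    formula_mono_mass,
)

__all__ = [
    "ModificationKind",
    "MODIFICATIONS",
    "Peptide",
    "ElementalComposition",
    "IsotopeEnvelope",
    "PeptideParseError",
    "parse_modified_sequence",
    "format_modified_sequence",
    "monoisotopic_mass",
    "mz",
    "neutral_mass",
    "elemental_composition",
    "isotope_envelope",
    "peptide_envelope",
]


class PeptideParseError(ValueError):
    """A modified-sequence string could not be interpreted."""


@dataclass(frozen=True)
class ModificationKind:
    """A named covalent modification with its mass and formula change."""

    name: str
    delta_composition: Mapping[str, int]
    allowed_residues: frozenset[str]
    n_term_only: bool = False

    @property
    def delta_mass(self) -> float:
        return formula_mono_mass(dict(self.delta_composition))


MODIFICATIONS: dict[str, ModificationKind] = {
    m.name: m
    for m in (
        ModificationKind("carbamidomethyl", {"C": 2, "H": 3, "N": 1, "O": 1}, frozenset("C")),
        ModificationKind("oxidation", {"O": 1}, frozenset("M")),
        ModificationKind("pyroglutamate_from_Q", {"N": -1, "H": -3}, frozenset("Q"), n_term_only=True),
        ModificationKind("pyroglutamate_from_E", {"H": -2, "O": -1}, frozenset("E"), n_term_only=True),
        ModificationKind("deamidation", {"H": -1, "N": -1, "O": 1}, frozenset("NQ")),
    )
}


@dataclass(frozen=True)
class Peptide:
    """A residue sequence with positioned modifications.

    ``mods`` is a tuple of ``(position, kind_name)`` with 1-based positions.
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residue(s): {sorted(bad)}")
        seen: set[tuple[int, str]] = set()
        for pos, kind_name in self.mods:
            kind = MODIFICATIONS.get(kind_name)
            if kind is None:
                raise ValueError(f"unknown modification {kind_name!r}")
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside [1, {len(self.sequence)}]")
            if kind.n_term_only and pos != 1:
                raise ValueError(f"{kind_name} allowed only at the N-terminus")
            if self.sequence[pos - 1] not in kind.allowed_residues:
                raise ValueError(
                    f"{kind_name} not allowed on {self.sequence[pos - 1]!r} at position {pos}"
                )
            if (pos, kind_name) in seen:
                raise ValueError(f"duplicate modification {kind_name} at position {pos}")
            seen.add((pos, kind_name))
        pyro_and_deam = {("pyroglutamate_from_Q", 1), ("deamidation", 1)}
        if pyro_and_deam <= {(k, p) for p, k in self.mods}:
            raise ValueError("pyroglutamate and deamidation are mutually exclusive at position 1")

    def __len__(self) -> int:
        return len(self.sequence)

    def mod_kinds_at(self, pos: int) -> tuple[str, ...]:
        return tuple(k for p, k in self.mods if p == pos)

    def without(self, kind_name: str) -> "Peptide":
        """Copy of this peptide with every modification of one kind removed."""
        return Peptide(self.sequence, tuple((p, k) for p, k in self.mods if k != kind_name))

    def deamidation_sites(self) -> tuple[int, ...]:
        return tuple(p for p, k in self.mods if k == "deamidation")


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts (C/H/N/O/S). Supports +/- and scalar multiplication."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "ElementalComposition":
        return cls(tuple(sorted((el, n) for el, n in d.items() if n != 0)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalComposition.from_dict(d)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
        return ElementalComposition.from_dict(d)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition.from_dict({el: n * k for el, n in self.counts})

    def mass(self) -> float:
        return formula_mono_mass(self.as_dict())

    def total_atoms(self) -> int:
        return sum(abs(n) for _, n in self.counts)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Theoretical isotopologue peaks of one elemental composition.

    ``peaks`` are ``(neutral_mass, relative_abundance)`` in increasing mass
    order, aggregated by nominal (integer) neutron excess with
    abundance-weighted centroid masses. The first peak is monoisotopic.
    """

    peaks: tuple[tuple[float, float], ...]
    origin: ElementalComposition

    @property
    def monoisotopic_mass(self) -> float:
        return self.peaks[0][0]

    def mz_peaks(self, charge: int) -> tuple[tuple[float, float], ...]:
        return tuple(((m + charge * PROTON_MASS) / charge, a) for m, a in self.peaks)


_TOKEN_RE = re.compile(r"([A-Za-z])(\(([+-])(\d*\.?\d+)\))?")

#: Matching tolerance for parenthesized mass deltas, mirroring the product-ion
#: tolerance of the upstream search (0.02 Da).
DELTA_MATCH_TOL = 0.02


def _match_delta(residue: str, at_n_term: bool, delta: float) -> str:
    """Resolve a reported mass delta to a modification kind for this residue."""
    best: tuple[float, str] | None = None
    for kind in MODIFICATIONS.values():
        if residue not in kind.allowed_residues:
            continue
        if kind.n_term_only and not at_n_term:
            continue
        err = abs(kind.delta_mass - delta)
        if err <= DELTA_MATCH_TOL and (best is None or err < best[0]):
            best = (err, kind.name)
    if best is None:
        raise PeptideParseError(
            f"delta {delta:+.4f} on residue {residue!r} matches no known modification"
        )
    return best[1]


def parse_modified_sequence(text: str, fixed_carbamidomethyl: bool = True) -> Peptide:
    """Parse a modified-sequence string of the search-export dialect.

    Grammar: ``LETTER ("(" SIGN DIGITS ["." DIGITS] ")")?`` repeated; each
    parenthesized signed delta modifies the preceding residue and must match
    a known modification within 0.02 Da. With ``fixed_carbamidomethyl`` every
    Cys is carbamidomethylated whether annotated or not (the upstream search
    treats it as a fixed modification).
    """
    if not text:
        raise PeptideParseError("empty sequence string")
    residues: list[str] = []
    mods: list[tuple[int, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos:
            raise PeptideParseError(f"malformed token at {text[pos:pos + 8]!r}")
        letter = m.group(1).upper()
        if letter not in CANONICAL_RESIDUES:
            raise PeptideParseError(f"unknown residue letter {m.group(1)!r}")
        residues.append(letter)
        if m.group(2):
            delta = float(m.group(4))
            if m.group(3) == "-":
                delta = -delta
            kind = _match_delta(letter, len(residues) == 1, delta)
            mods.append((len(residues), kind))
        pos = m.end()
    if fixed_carbamidomethyl:
        annotated = {p for p, k in mods if k == "carbamidomethyl"}
        for i, aa in enumerate(residues, start=1):
            if aa == "C" and i not in annotated:
                mods.append((i, "carbamidomethyl"))
    return Peptide("".join(residues), tuple(sorted(mods)))


def format_modified_sequence(p: Peptide, include_carbamidomethyl: bool = True) -> str:
    """Canonical string form; inverse of :func:`parse_modified_sequence`.

    Deltas are printed with 2 decimals, e.g. ``"Q(-17.03)"``.
    """
    by_pos: dict[int, list[str]] = {}
    for pos, kind in p.mods:
        if kind == "carbamidomethyl" and not include_carbamidomethyl:
            continue
        by_pos.setdefault(pos, []).append(kind)
    out: list[str] = []
    for i, aa in enumerate(p.sequence, start=1):
        out.append(aa)
        for kind in by_pos.get(i, ()):
            d = MODIFICATIONS[kind].delta_mass
            out.append(f"({d:+.2f})")
    return "".join(out)


def elemental_composition(p: Peptide) -> ElementalComposition:
    """Formula of the intact (neutral) modified peptide: residues + H2O + mods."""
    d: dict[str, int] = dict(WATER_FORMULA)
    for aa in p.sequence:
        for el, n in RESIDUE_FORMULA[aa].items():
            d[el] = d.get(el, 0) + n
    for _, kind_name in p.mods:
        for el, n in MODIFICATIONS[kind_name].delta_composition.items():
            d[el] = d.get(el, 0) + n
    if any(n < 0 for n in d.values()):
        raise ValueError("modifications leave a negative element count")
    return ElementalComposition.from_dict(d)


def monoisotopic_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass in Da: residues + water + modification deltas."""
    m = WATER_MASS + sum(RESIDUE_MASS[aa] for aa in p.sequence)
    m += sum(MODIFICATIONS[k].delta_mass for _, k in p.mods)
    return m


def mz(mass: float, charge: int) -> float:
    """m/z of the [M + charge·H]^charge+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def neutral_mass(mz_value: float, charge: int) -> float:
    """Neutral mass from an observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return charge * mz_value - charge * PROTON_MASS


def _element_distribution(el: str, n: int, max_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """(abundance, mass-moment) arrays over neutron-excess bins for ``el``_n.

    Computed by exponentiation-by-squaring of the single-atom distribution.
    ``moment[k]`` is the abundance-weighted total mass of bin ``k``, so the
    centroid is ``moment[k] / abundance[k]``.
    """
    isotopes = ISOTOPES[el]
    base_mass = isotopes[0][0]
    width = round(isotopes[-1][0] - base_mass) + 1
    a1 = np.zeros(width)
    m1 = np.zeros(width)
    for i, (mass_i, ab) in enumerate(isotopes):
        # bin by nominal neutron excess relative to the lightest isotope
        k = round(mass_i - base_mass)
        a1[k] += ab
        m1[k] += ab * (mass_i - base_mass)  # store mass excess; base added later
    abund = np.array([1.0])
    moment = np.array([0.0])
    sq_a, sq_m = a1, m1
    e = n
    while e:
        if e & 1:
            abund, moment = _convolve_pair(abund, moment, sq_a, sq_m, max_bins)
        e >>= 1
        if e:
            sq_a, sq_m = _convolve_pair(sq_a, sq_m, sq_a, sq_m, max_bins)
    # moment currently tracks summed mass-excess; add n * base_mass
    moment = moment + abund * n * base_mass
    return abund, moment


def _convolve_pair(
    a: np.ndarray, ma: np.ndarray, b: np.ndarray, mb: np.ndarray, max_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    abund = np.convolve(a, b)[:max_bins]
    moment = (np.convolve(ma, b) + np.convolve(a, mb))[:max_bins]
    return abund, moment


@lru_cache(maxsize=4096)
def _envelope_cached(
    counts: tuple[tuple[str, int], ...], prune_threshold: float, max_peaks: int
) -> tuple[tuple[float, float], ...]:
    # generous working width: retained peaks never extend past ~4x max_peaks
    max_bins = max(4 * max_peaks, 16)
    abund = np.array([1.0])
    moment = np.array([0.0])
    for el, n in counts:
        if el not in ISOTOPES:
            raise ValueError(f"unknown element {el!r}")
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
        ea, em = _element_distribution(el, n, max_bins)
        abund, moment = _convolve_pair(abund, moment, ea, em, max_bins)
    peaks = [
        (moment[k] / abund[k], float(abund[k]))
        for k in range(len(abund))
        if abund[k] > prune_threshold
    ]
    return tuple(peaks[:max_peaks])


def isotope_envelope(
    c: ElementalComposition,
    prune_threshold: float = 1e-10,
    max_peaks: int = 10,
    renormalize: bool = False,
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of a composition.

    Peaks are aggregated by integer neutron-excess bins; each bin's reported
    mass is the abundance-weighted centroid. Peaks below ``prune_threshold``
    are dropped and at most ``max_peaks`` are kept (abundances stay raw
    unless ``renormalize``).
    """
    if not c.counts:
        raise ValueError("empty composition")
    if not 0 <= prune_threshold < 0.01:
        raise ValueError("prune_threshold must be in [0, 0.01)")
    peaks = _envelope_cached(c.counts, prune_threshold, max_peaks)
    if renormalize:
        total = sum(a for _, a in peaks)
        peaks = tuple((m, a / total) for m, a in peaks)
    return IsotopeEnvelope(peaks, c)


def peptide_envelope(p: Peptide, **kwargs) -> IsotopeEnvelope:
    """Convenience wrapper: envelope of a peptide's elemental composition."""
    return isotope_envelope(elemental_composition(p), **kwargs)
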