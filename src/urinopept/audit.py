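"""Adjudication of deamidation assignments from MS evidence.

Search engines frequently mis-assign native peptides as deamidated: the mass
difference between a deamidated peptide and the second isotopic peak of the
native peptide (one 13C) is only 0.0193 Da, so when the instrument selects a
non-monoisotopic precursor peak the engine may explain the +1.003 Da offset
as deamidation (+0.984 Da) instead. This module codifies the adjudication:

MS1 stage
  Rule 1 (``monoisotopic_native_visible``): if the MS1 spectrum shows a peak
  at the native monoisotopic m/z and the fragmented precursor sits on a
  native isotope position (native + j·1.003355, j ≥ 1), the record is
  reassigned to the native sequence.
  Rule 2 (``closer_to_native_isotope``): otherwise, if the observed neutral
  mass is strictly closer to some native isotopologue (j ≥ 1) than to any
  deamidated isotopologue (i ≥ 0), it is likewise reassigned.

MS2 stage
  Deferred records are checked for site-determining fragment ions: fragments
  whose mass differs between the native and the site-deamidated form. If
  exactly one candidate Gln/Asn site is supported by at least
  ``min_site_ions`` deamidated-form fragments (that do not also match the
  native form), deamidation is confirmed at that site; otherwise the record
  is excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._constants import C13_DELTA, DEAMIDATION_DELTA, PROTON_MASS, RESIDUE_MASS, WATER_MASS
from .chem import (
    IsotopeEnvelope,
    MODIFICATIONS,
    Peptide,
    elemental_composition,
    isotope_envelope,
    monoisotopic_mass,
    mz,
    neutral_mass,
)

__all__ = [
    "AuditConfig",
    "PrecursorObservation",
    "SpectrumPeakList",
    "AdjudicationResult",
    "Verdict",
    "theoretical_pair",
    "adjudicate_ms1",
    "site_determining_ions",
    "adjudicate",
]


class Verdict:
    NATIVE_REASSIGNED = "NATIVE_REASSIGNED"
    DEAMIDATED_CONFIRMED = "DEAMIDATED_CONFIRMED"
    AMBIGUOUS_EXCLUDED = "AMBIGUOUS_EXCLUDED"
    NATIVE_UNFLAGGED = "NATIVE_UNFLAGGED"


@dataclass(frozen=True)
class AuditConfig:
    """Tolerances and limits of the adjudication.

    Defaults mirror the upstream search: 10 ppm precursor, 0.02 Da fragment
    tolerance, isotope mispicks up to the third isotopic peak, and at least
    two site-determining fragment ions to localize a deamidation.
    """

    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02
    max_isotope_index: int = 3
    min_site_ions: int = 2
    c13_delta: float = C13_DELTA
    deam_delta: float = DEAMIDATION_DELTA
    charge_range: tuple[int, int] = (2, 7)

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_isotope_index < 1:
            raise ValueError("max_isotope_index must be >= 1")


@dataclass(frozen=True)
class PrecursorObservation:
    """The precursor ion selected for fragmentation."""

    mz: float
    charge: int

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def neutral_mass(self) -> float:
        return neutral_mass(self.mz, self.charge)


@dataclass(frozen=True)
class SpectrumPeakList:
    """An MS1 or MS2 peak list: (m/z, intensity) with strictly increasing m/z."""

    level: str  # "MS1" | "MS2"
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.level not in ("MS1", "MS2"):
            raise ValueError(f"level must be MS1 or MS2, got {self.level!r}")
        mzs = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak m/z values must be strictly increasing")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("intensities must be non-negative")

    def has_peak_near(self, target_mz: float, tol_da: float) -> bool:
        return any(abs(m - target_mz) <= tol_da for m, _ in self.peaks)


@dataclass(frozen=True)
class AdjudicationResult:
    """Verdict plus the numeric evidence trail behind it."""

    verdict: str
    rule_fired: str
    evidence: dict = field(default_factory=dict)


def theoretical_pair(
    p: Peptide, prune_threshold: float = 1e-10, max_peaks: int = 10
) -> tuple[tuple[float, IsotopeEnvelope], tuple[float, IsotopeEnvelope]]:
    """(native, deamidated) theoretical (mass, envelope) pair for an audit.

    ``p`` must carry at least one deamidation; the native form is ``p`` with
    all deamidations stripped.
    """
    k = len(p.deamidation_sites())
    if k == 0:
        raise ValueError("peptide carries no deamidation: nothing to audit")
    native = p.without("deamidation")
    native_mass = monoisotopic_mass(native)
    deam_mass = monoisotopic_mass(p)
    native_env = isotope_envelope(elemental_composition(native), prune_threshold, max_peaks)
    deam_env = isotope_envelope(elemental_composition(p), prune_threshold, max_peaks)
    return (native_mass, native_env), (deam_mass, deam_env)


def adjudicate_ms1(
    p: Peptide,
    obs: PrecursorObservation,
    ms1: SpectrumPeakList | None,
    cfg: AuditConfig = AuditConfig(),
) -> AdjudicationResult:
    """MS1-level adjudication (Rules 1 and 2); may defer to the MS2 stage."""
    if not p.deamidation_sites():
        return AdjudicationResult(Verdict.NATIVE_UNFLAGGED, "not_applicable")
    (native_mass, _), (deam_mass, _) = theoretical_pair(p)
    obs_mass = obs.neutral_mass
    tol_da = cfg.precursor_tol_ppm * 1e-6 * obs_mass

    # Rule 1: native monoisotopic visible in MS1 and precursor on a native
    # isotope position.
    j_hit = None
    for j in range(1, cfg.max_isotope_index + 1):
        if abs(obs_mass - (native_mass + j * cfg.c13_delta)) <= tol_da:
            j_hit = j
            break
    if ms1 is not None and ms1.peaks and j_hit is not None:
        native_mz = mz(native_mass, obs.charge)
        if ms1.has_peak_near(native_mz, tol_da / obs.charge):
            return AdjudicationResult(
                Verdict.NATIVE_REASSIGNED,
                "monoisotopic_native_visible",
                {
                    "isotope_index": j_hit,
                    "mass_error_da": obs_mass - (native_mass + j_hit * cfg.c13_delta),
                    "native_mass": native_mass,
                    "deamidated_mass": deam_mass,
                },
            )

    # Rule 2: observed mass strictly closer to a native isotopologue than to
    # any deamidated isotopologue. Equality defers to MS2 (conservative).
    d_native, j_best = min(
        (abs(obs_mass - (native_mass + j * cfg.c13_delta)), j)
        for j in range(1, cfg.max_isotope_index + 1)
    )
    d_deam, i_best = min(
        (abs(obs_mass - (deam_mass + i * cfg.c13_delta)), i)
        for i in range(0, cfg.max_isotope_index + 1)
    )
    evidence = {
        "native_distance_da": d_native,
        "native_isotope_index": j_best,
        "deamidated_distance_da": d_deam,
        "deamidated_isotope_index": i_best,
        "native_mass": native_mass,
        "deamidated_mass": deam_mass,
    }
    if d_native < d_deam:
        return AdjudicationResult(Verdict.NATIVE_REASSIGNED, "closer_to_native_isotope", evidence)
    return AdjudicationResult(Verdict.AMBIGUOUS_EXCLUDED, "ms2_inconclusive", evidence)


_NH3 = 17.026549
_SERIES = ("b", "y", "c", "z")


def _fragment_mass(sequence: str, mods: Sequence[tuple[int, str]], end: int, series: str) -> float:
    """Singly-protonated fragment mass for a prefix (b/c) or suffix (y/z) ion.

    ``end`` is the fragment length (number of residues from the relevant
    terminus). Formulas: b = Σresidues + proton; y = Σresidues + water +
    proton; c = b + NH3; z• = y − NH3 + H.
    """
    n = len(sequence)
    if series in ("b", "c"):
        span = range(1, end + 1)
    else:
        span = range(n - end + 1, n + 1)
    total = sum(RESIDUE_MASS[sequence[i - 1]] for i in span)
    total += sum(MODIFICATIONS[k].delta_mass for pos, k in mods if pos in span)
    if series == "b":
        return total + PROTON_MASS
    if series == "c":
        return total + PROTON_MASS + _NH3
    if series == "y":
        return total + WATER_MASS + PROTON_MASS
    if series == "z":
        return total + WATER_MASS + PROTON_MASS - _NH3 + 1.00782503207
    raise ValueError(f"unknown series {series!r}")


def site_determining_ions(
    p: Peptide, site: int, series: str = "b"
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Theoretical fragments distinguishing native vs deamidated-at-``site``.

    Returns ``(native_masses, deamidated_masses)`` for the fragments of the
    requested series that cover the site but not the full peptide, i.e. the
    fragments whose mass differs between the two candidate forms.
    """
    if series not in _SERIES:
        raise ValueError(f"series must be one of {_SERIES}")
    if not 1 <= site <= len(p):
        raise ValueError(f"site {site} outside peptide")
    if p.sequence[site - 1] not in "NQ":
        raise ValueError(f"site {site} is {p.sequence[site - 1]!r}, not N/Q")
    if site == 1 and any(k.startswith("pyroglutamate") for k in p.mod_kinds_at(1)):
        raise ValueError("pyroglutamate and deamidation are mutually exclusive at position 1")
    base_mods = tuple((pos, k) for pos, k in p.mods if k != "deamidation")
    deam_mods = base_mods + ((site, "deamidation"),)
    n = len(p)
    native, deam = [], []
    if series in ("b", "c"):
        lengths = range(site, n)  # full-length prefix is not a fragment
    else:
        lengths = range(n - site + 1, n)
    for L in lengths:
        native.append(_fragment_mass(p.sequence, base_mods, L, series))
        deam.append(_fragment_mass(p.sequence, deam_mods, L, series))
    return tuple(native), tuple(deam)


def _count_site_ions(
    p: Peptide, site: int, ms2: SpectrumPeakList, cfg: AuditConfig
) -> int:
    """MS2 peaks matching deamidated-form site ions but not the native form."""
    hits = 0
    for series in _SERIES:
        native, deam = site_determining_ions(p, site, series)
        for m_nat, m_deam in zip(native, deam):
            for m_obs, _ in ms2.peaks:
                if abs(m_obs - m_deam) <= cfg.fragment_tol_da and not (
                    abs(m_obs - m_nat) <= cfg.fragment_tol_da
                ):
                    hits += 1
                    break
    return hits


def adjudicate(
    p: Peptide,
    obs: PrecursorObservation,
    ms1: SpectrumPeakList | None,
    ms2: SpectrumPeakList | None = None,
    cfg: AuditConfig = AuditConfig(),
) -> AdjudicationResult:
    """Full MS1 + MS2 adjudication of one deamidation-flagged record."""
    result = adjudicate_ms1(p, obs, ms1, cfg)
    if result.verdict != Verdict.AMBIGUOUS_EXCLUDED:
        return result
    if ms2 is None or not ms2.peaks:
        return AdjudicationResult(
            Verdict.AMBIGUOUS_EXCLUDED,
            "ms2_inconclusive",
            {**result.evidence, "reason": "no MS2 spectrum"},
        )
    candidates = [i + 1 for i, aa in enumerate(p.sequence) if aa in "NQ"]
    candidates = [
        s for s in candidates
        if not (s == 1 and any(k.startswith("pyroglutamate") for k in p.mod_kinds_at(1)))
    ]
    support = {s: _count_site_ions(p, s, ms2, cfg) for s in candidates}
    confirmed = [s for s, n in support.items() if n >= cfg.min_site_ions]
    if len(confirmed) == 1:
        return AdjudicationResult(
            Verdict.DEAMIDATED_CONFIRMED,
            "ms2_site_confirmed",
            {**result.evidence, "site": confirmed[0], "site_ion_counts": support},
        )
    return AdjudicationResult(
        Verdict.AMBIGUOUS_EXCLUDED,
        "ms2_inconclusive",
        {**result.evidence, "site_ion_counts": support},
    )
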