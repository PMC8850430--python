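"""File dialects: identification CSV, peak-list TSV, and batch audit output.

The identification table is a search-export-like CSV with required columns
``sample, sequence, mz, z`` (configurable via a dialect map); peak lists are
tab-separated ``spectrum_id, level, mz, intensity`` rows.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .assign import IdentificationRecord
from .audit import AdjudicationResult, AuditConfig, PrecursorObservation, SpectrumPeakList, adjudicate
from .chem import PeptideParseError, parse_modified_sequence

__all__ = [
    "read_identifications",
    "read_peak_lists",
    "audit_records",
]

logger = logging.getLogger("urinopept")

REQUIRED_COLUMNS = ("sample", "sequence", "mz", "z")
OPTIONAL_COLUMNS = ("replicate", "spectrum_id", "score", "accessions")


def read_identifications(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    charge_range: tuple[int, int] = (2, 7),
    strict: bool = False,
) -> list[IdentificationRecord]:
    """Parse an identification CSV into records.

    ``dialect`` maps the standard column names to the file's actual ones.
    Rows with a charge outside ``charge_range`` are skipped with a logged
    warning; an unparseable sequence raises (naming the row) when
    ``strict``, else skips.
    """
    df = pd.read_csv(path)
    colmap = {std: (dialect or {}).get(std, std) for std in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    missing = [c for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    records: list[IdentificationRecord] = []
    for i, row in df.iterrows():
        charge = int(row[colmap["z"]])
        if not charge_range[0] <= charge <= charge_range[1]:
            logger.warning("row %d: SKIP_CHARGE charge=%d outside %s", i, charge, charge_range)
            continue
        text = str(row[colmap["sequence"]])
        try:
            peptide = parse_modified_sequence(text)
        except PeptideParseError as exc:
            if strict:
                raise ValueError(f"row {i}: unparseable sequence {text!r}: {exc}") from exc
            logger.warning("row %d: SKIP_PARSE %s", i, exc)
            continue
        records.append(
            IdentificationRecord(
                sample_id=str(row[colmap["sample"]]),
                sequence_text=text,
                peptide=peptide,
                precursor_mz=float(row[colmap["mz"]]),
                charge=charge,
                score=float(row[colmap["score"]]) if colmap["score"] in df.columns else 0.0,
                replicate=str(row[colmap["replicate"]]) if colmap["replicate"] in df.columns else "1",
                spectrum_id=str(row[colmap["spectrum_id"]]) if colmap["spectrum_id"] in df.columns else f"row{i}",
            )
        )
    return records


def read_peak_lists(path: str | Path) -> dict[tuple[str, str], SpectrumPeakList]:
    """Read a peak-list TSV into per-(spectrum, level) peak lists."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], SpectrumPeakList] = {}
    for (sid, level), sub in df.groupby(["spectrum_id", "level"]):
        sub = sub.sort_values("mz")
        out[(str(sid), str(level))] = SpectrumPeakList(
            str(level), tuple(zip(sub["mz"].tolist(), sub["intensity"].tolist()))
        )
    return out


def audit_records(
    records: Sequence[IdentificationRecord],
    spectra: Mapping[tuple[str, str], SpectrumPeakList] | None = None,
    cfg: AuditConfig = AuditConfig(),
) -> pd.DataFrame:
    """Adjudicate every record; returns a stable, sorted audit table.

    Unflagged records (no deamidation reported) pass through with verdict
    ``NATIVE_UNFLAGGED``.
    """
    spectra = spectra or {}
    rows = []
    for rec in records:
        obs = PrecursorObservation(rec.precursor_mz, rec.charge)
        if not rec.peptide.deamidation_sites():
            result = AdjudicationResult("NATIVE_UNFLAGGED", "not_applicable")
        else:
            ms1 = spectra.get((rec.spectrum_id, "MS1"))
            ms2 = spectra.get((rec.spectrum_id, "MS2"))
            result = adjudicate(rec.peptide, obs, ms1, ms2, cfg)
        ev = result.evidence
        rows.append({
            "spectrum_id": rec.spectrum_id,
            "sample": rec.sample_id,
            "replicate": rec.replicate,
            "sequence": rec.sequence_text,
            "verdict": result.verdict,
            "rule_fired": result.rule_fired,
            "native_mass": ev.get("native_mass", float("nan")),
            "deamidated_mass": ev.get("deamidated_mass", float("nan")),
            "native_distance_da": ev.get("native_distance_da", float("nan")),
            "deamidated_distance_da": ev.get("deamidated_distance_da", float("nan")),
            "isotope_index": ev.get("isotope_index", ev.get("native_isotope_index", 0)),
            "confirmed_site": ev.get("site", 0),
        })
        if result.verdict == "AMBIGUOUS_EXCLUDED":
            logger.info("spectrum %s: EXCLUDE_AMBIGUOUS_DEAMIDATION", rec.spectrum_id)
    df = pd.DataFrame(rows)
    return df.sort_values(["sample", "spectrum_id"], kind="mergesort").reset_index(drop=True)
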