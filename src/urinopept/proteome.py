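"""Protein databases: FASTA I/O, keyword-filtered merging, substring lookup.

The search databases mirror how grain peptidomics databases are curated:
every manually curated (SwissProt-tier) record is kept, while automatically
annotated (TrEMBL-tier) records are kept only when their description
mentions a storage-protein keyword (gliadin, glutenin, secalin, hordein).

Peptide-to-proteome lookup supports an isoleucine/leucine equivalence mode,
because the two residues are isobaric and indistinguishable by CID/EThcD
fragmentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "ProteomeDB",
    "read_fasta",
    "write_fasta",
    "build_database",
    "find_matches",
    "DEFAULT_KEYWORDS",
]

DEFAULT_KEYWORDS = ("gliadin", "glutenin", "secalin", "hordein")

_IL_TABLE = str.maketrans({"I": "L"})


def collapse_il(sequence: str) -> str:
    """Collapse the isobaric I/L pair to the single reported symbol L."""
    return sequence.translate(_IL_TABLE)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str
    taxon: str = ""
    tier: str = "curated"  # curated | automatic

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession!r}")
        odd = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWYUX")
        if odd:
            raise ValueError(f"invalid residues {sorted(odd)} in {self.accession!r}")
        if set(self.sequence) & set("UX"):
            warnings.warn(f"{self.accession}: non-standard residues (U/X) present")


def _parse_header(header: str) -> tuple[str, str]:
    """Extract (accession, description) from a UniProt-dialect FASTA header.

    ``db|ACC|NAME description`` yields NAME-style accession if present,
    otherwise the first whitespace-delimited token.
    """
    first, _, description = header.partition(" ")
    parts = first.split("|")
    accession = parts[2] if len(parts) >= 3 else first
    return accession, description.strip()


def read_fasta(path: str | Path, tier: str = "curated", taxon: str = "") -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords (duplicates: warn, keep first)."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, description = _parse_header(rec.description)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence after header {rec.description!r}")
        if accession in seen:
            warnings.warn(f"duplicate accession {accession!r}: keeping first")
            continue
        seen.add(accession)
        records.append(ProteinRecord(accession, description, seq, taxon, tier))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"up|{r.accession}|{r.accession}", description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta-2line")


@dataclass
class ProteomeDB:
    """An indexed protein collection supporting I/L-equivalent substring lookup."""

    records: list[ProteinRecord]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_accession = {r.accession: r for r in self.records}
        self._collapsed = {r.accession: collapse_il(r.sequence) for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def get(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    def lookup(self, peptide_sequence: str, il_equivalent: bool = True) -> list[tuple[str, int]]:
        """All (accession, 1-based start) whose sequence contains the peptide."""
        hits: list[tuple[str, int]] = []
        query = collapse_il(peptide_sequence) if il_equivalent else peptide_sequence
        for rec in self.records:
            subject = self._collapsed[rec.accession] if il_equivalent else rec.sequence
            start = subject.find(query)
            while start != -1:
                hits.append((rec.accession, start + 1))
                start = subject.find(query, start + 1)
        hits.sort()
        return hits

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def build_database(
    curated_files: Sequence[str | Path] = (),
    automatic_files: Sequence[str | Path] = (),
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    curated_records: Sequence[ProteinRecord] = (),
    automatic_records: Sequence[ProteinRecord] = (),
) -> ProteomeDB:
    """Merge curated and keyword-filtered automatic records into one database.

    Curated records are always retained. Automatic records are retained only
    if the description contains at least one keyword (case-insensitive
    substring). Duplicated accessions keep the curated tier.
    """
    curated: list[ProteinRecord] = list(curated_records)
    for f in curated_files:
        curated.extend(read_fasta(f, tier="curated"))
    automatic: list[ProteinRecord] = list(automatic_records)
    for f in automatic_files:
        automatic.extend(read_fasta(f, tier="automatic"))

    kw = [k.lower() for k in keywords]
    kept: dict[str, ProteinRecord] = {}
    for rec in sorted(curated, key=lambda r: r.accession):
        kept.setdefault(rec.accession, rec)
    n_auto_kept = 0
    for rec in sorted(automatic, key=lambda r: r.accession):
        desc = rec.description.lower()
        if any(k in desc for k in kw):
            if rec.accession not in kept:
                kept[rec.accession] = ProteinRecord(
                    rec.accession, rec.description, rec.sequence, rec.taxon, "automatic"
                )
                n_auto_kept += 1
    if not kept:
        raise ValueError("no records survive database construction")
    manifest = {
        "curated_files": sorted(str(f) for f in curated_files),
        "automatic_files": sorted(str(f) for f in automatic_files),
        "keywords": sorted(kw),
        "n_curated": len(kept) - n_auto_kept,
        "n_automatic_kept": n_auto_kept,
        "n_records": len(kept),
    }
    return ProteomeDB(sorted(kept.values(), key=lambda r: r.accession), manifest)


def find_matches(
    peptide_sequence: str, db: ProteomeDB, il_equivalent: bool = True
) -> list[tuple[str, int]]:
    """All occurrences of a peptide in a database, sorted by accession then offset.

    Peptides shorter than 5 residues are never matched (below the shortest
    motif the pipeline scans); an empty list is returned.
    """
    if len(peptide_sequence) < 5:
        return []
    return db.lookup(peptide_sequence, il_equivalent=il_equivalent)
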