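"""Species assignment of identified peptides.

Precedence rules:

1. A peptide containing the subsequence ``YVRPD`` is human — this motif
   belongs to the immunoglobulin heavy-chain joining region, and peptides
   carrying it appear regardless of gluten intake, so even a peptide that
   maps uniquely to a grain proteome is treated as human.
2. Any match in the human database makes the peptide human.
3. Otherwise a grain-database match assigns the peptide to that grain
   (a peptide is "wheat" only if it maps to wheat and not to human).
4. No match at all: unmatched.

Grain-vs-grain classification for multi-grain challenge studies labels each
peptide by exclusive membership; peptides mapping to more than one grain
proteome are flagged and excluded from unique-count outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem import Peptide, parse_modified_sequence
from .proteome import ProteomeDB, collapse_il, find_matches

__all__ = [
    "IdentificationRecord",
    "Assignment",
    "IG_MOTIF",
    "assign_species",
    "unique_grain_classification",
    "repertoire_key",
    "sample_repertoire",
]

IG_MOTIF = "YVRPD"

MIN_LOOKUP_LENGTH = 5


@dataclass(frozen=True)
class IdentificationRecord:
    """One row of a search-engine identification export."""

    sample_id: str
    sequence_text: str
    peptide: Peptide
    precursor_mz: float
    charge: int
    score: float = 0.0
    replicate: str = "1"
    engine_accessions: tuple[str, ...] = ()  # advisory only; never used for assignment
    spectrum_id: str = ""

    @classmethod
    def from_text(
        cls, sample_id: str, sequence_text: str, precursor_mz: float, charge: int, **kwargs
    ) -> "IdentificationRecord":
        return cls(
            sample_id, sequence_text, parse_modified_sequence(sequence_text),
            precursor_mz, charge, **kwargs,
        )


@dataclass(frozen=True)
class Assignment:
    species: str  # human | wheat | barley | rye | unmatched
    matches: tuple[tuple[str, str, int], ...]  # (db_label, accession, 1-based start)
    rule_trail: tuple[str, ...]


def assign_species(
    sequence: str,
    human_db: ProteomeDB | None,
    grain_dbs: Mapping[str, ProteomeDB],
    il_equivalent: bool = True,
) -> Assignment:
    """Assign a native peptide sequence to human or one grain species."""
    trail: list[str] = []
    matches: list[tuple[str, str, int]] = []
    for label, db in grain_dbs.items():
        for acc, off in find_matches(sequence, db, il_equivalent=il_equivalent):
            matches.append((label, acc, off))
    human_hits: list[tuple[str, str, int]] = []
    if human_db is not None:
        human_hits = [
            ("human", acc, off)
            for acc, off in find_matches(sequence, human_db, il_equivalent=il_equivalent)
        ]
        matches.extend(human_hits)

    if len(sequence) < MIN_LOOKUP_LENGTH:
        trail.append("below_min_length")
        return Assignment("unmatched", tuple(matches), tuple(trail))

    if IG_MOTIF in sequence:
        trail.append("ig_motif")
        return Assignment("human", tuple(matches), tuple(trail))
    trail.append("no_ig_motif")

    if human_hits:
        trail.append("human_db_match")
        return Assignment("human", tuple(matches), tuple(trail))
    trail.append("no_human_db_match")

    grain_labels = sorted({label for label, _, _ in matches if label != "human"})
    if grain_labels:
        # peptides hitting several grain DBs keep every match; the species
        # label follows the first grain in the caller's (insertion) order
        for label in grain_dbs:
            if label in grain_labels:
                trail.append(f"grain_db_match:{'+'.join(grain_labels)}")
                return Assignment(label, tuple(matches), tuple(trail))
    trail.append("unmatched")
    return Assignment("unmatched", tuple(matches), tuple(trail))


def unique_grain_classification(
    sequence: str,
    grain_dbs: Mapping[str, ProteomeDB],
    challenge: str | None = None,
    il_equivalent: bool = True,
) -> tuple[str, str]:
    """Exclusive grain membership label plus an annotation.

    Returns ``(label, note)`` where label is ``"<grain>_only"``,
    ``"shared_excluded"`` or ``"unmatched"``. When the sample's dietary
    ``challenge`` grain is known and differs from the (unique) matching
    proteome, the note flags a possible unannotated origin — e.g. a
    rye-challenge peptide found only in the wheat proteome.
    """
    hits = {
        label
        for label, db in grain_dbs.items()
        if find_matches(sequence, db, il_equivalent=il_equivalent)
    }
    if not hits:
        return "unmatched", ""
    if len(hits) > 1:
        return "shared_excluded", "+".join(sorted(hits))
    only = next(iter(hits))
    note = ""
    if challenge is not None and challenge != only:
        note = f"possible unannotated {challenge} origin"
    return f"{only}_only", note


def repertoire_key(p: Peptide) -> str:
    """Distinctness key for repertoire counting.

    The key is the native residue string with I/L collapsed; modifications
    are ignored except N-terminal pyroglutamate, which marks a chemically
    distinct stabilized form and is kept as a prefix tag.
    """
    key = collapse_il(p.sequence)
    if any(k.startswith("pyroglutamate") for k in p.mod_kinds_at(1)):
        key = "pyr-" + key
    return key


def sample_repertoire(
    records: Sequence[IdentificationRecord],
    verdicts: Mapping[str, str] | None = None,
    aggregate_replicates: bool = True,
) -> dict[str, set[str]]:
    """Per-sample sets of distinct peptide keys.

    ``verdicts`` maps record spectrum ids to audit verdicts; records judged
    ``AMBIGUOUS_EXCLUDED`` are dropped, and reassigned records contribute
    their native sequence (the key is native-form regardless). Without
    replicate aggregation, keys are per ``(sample, replicate)`` joined as
    ``sample/replicate``.
    """
    out: dict[str, set[str]] = {}
    for rec in records:
        if verdicts is not None and verdicts.get(rec.spectrum_id) == "AMBIGUOUS_EXCLUDED":
            continue
        native = rec.peptide.without("deamidation")
        key = repertoire_key(native)
        sample = rec.sample_id if aggregate_replicates else f"{rec.sample_id}/{rec.replicate}"
        out.setdefault(sample, set()).add(key)
    return out
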