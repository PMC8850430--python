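"""Immunological annotation of gluten peptides.

Three kinds of annotation are supported:

* **T-cell epitopes** — a catalogue of 17 nine-residue core sequences
  presented by HLA-DQ2/DQ8 and recognized by celiac-patient T cells,
  matched as exact native (Gln-form) substrings.
* **Antibody motifs** — the recognition motifs of the monoclonal antibodies
  used in commercial gluten assays: R5 ``QXP(W/F)P``, G12 ``QPQLP(Y/F)``
  and A1 ``QLP(Y/F)PQP``.
* **Innate-response family** — relationship to the 20-mer
  ``GQQQPFPPQQPYPQPQPFPS``, the alpha-gliadin peptide family that
  stimulates innate immune responses and appears in essentially every
  gluten-challenged urine sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Epitope",
    "load_epitope_catalogue",
    "scan_epitopes",
    "scan_antibody_motifs",
    "epitope_count_table",
    "innate_family",
    "INNATE_20MER",
    "ANTIBODY_MOTIFS",
]

INNATE_20MER = "GQQQPFPPQQPYPQPQPFPS"

#: Minimum residues of overlap with the 20-mer for a truncation/extension
#: variant call.
INNATE_MIN_OVERLAP = 15

ANTIBODY_MOTIFS: dict[str, str] = {
    "R5": r"Q.P[WF]P",
    "G12": r"QPQLP[YF]",
    "A1": r"QLP[YF]PQP",
}


@dataclass(frozen=True)
class Epitope:
    name: str
    sequence: str


def load_epitope_catalogue(path: str | None = None) -> tuple[Epitope, ...]:
    """Load the versioned epitope catalogue TSV (name, sequence)."""
    if path is None:
        source = resources.files("urinopept.data").joinpath("epitopes_v1.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return tuple(Epitope(r["name"], r["sequence"]) for _, r in df.iterrows())


def scan_epitopes(
    sequence: str, catalogue: Sequence[Epitope] | None = None
) -> list[tuple[str, str, int]]:
    """All exact (overlapping) epitope occurrences: (name, epitope_seq, 1-based start)."""
    if catalogue is None:
        catalogue = load_epitope_catalogue()
    hits: list[tuple[str, str, int]] = []
    for epi in catalogue:
        start = sequence.find(epi.sequence)
        while start != -1:
            hits.append((epi.name, epi.sequence, start + 1))
            start = sequence.find(epi.sequence, start + 1)
    hits.sort(key=lambda h: (h[2], h[0]))
    return hits


def scan_antibody_motifs(sequence: str) -> list[tuple[str, int]]:
    """All antibody-motif matches: (motif name, 1-based start), overlaps included."""
    hits: list[tuple[str, int]] = []
    for name, pattern in ANTIBODY_MOTIFS.items():
        for m in re.finditer(f"(?=({pattern}))", sequence):
            hits.append((name, m.start() + 1))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def innate_family(sequence: str) -> str:
    """Classify a sequence against the innate-response 20-mer family.

    ``"exact"`` for the 20-mer itself; ``"variant"`` when the sequence
    contains the 20-mer or is contained in it with at least
    ``INNATE_MIN_OVERLAP`` residues of overlap (a truncation or extension);
    ``"unrelated"`` otherwise.
    """
    ref = INNATE_20MER
    if sequence == ref:
        return "exact"
    if ref in sequence:
        return "variant"
    if sequence in ref and len(sequence) >= INNATE_MIN_OVERLAP:
        return "variant"
    # sliding overlap: longest run shared at either end of a containment-free
    # alignment cannot exceed a full substring; check windowed containment
    for L in range(min(len(ref), len(sequence)), INNATE_MIN_OVERLAP - 1, -1):
        for start in range(len(ref) - L + 1):
            if ref[start:start + L] in sequence:
                return "variant"
    return "unrelated"


def epitope_count_table(
    group_repertoires: Mapping[str, Iterable[str]],
    catalogue: Sequence[Epitope] | None = None,
) -> pd.DataFrame:
    """Distinct-peptide counts per epitope per group.

    ``group_repertoires`` maps group label to the group's union repertoire
    (distinct peptide sequences). A cell counts the group's distinct
    peptides containing at least one occurrence of the epitope.
    """
    if catalogue is None:
        catalogue = load_epitope_catalogue()
    if any(not list(rep) for rep in group_repertoires.values()):
        empty = [g for g, rep in group_repertoires.items() if not list(rep)]
        raise ValueError(f"empty group(s): {empty}")
    data = {
        group: [
            sum(1 for pep in repertoire if epi.sequence in pep) for epi in catalogue
        ]
        for group, repertoire in group_repertoires.items()
    }
    return pd.DataFrame(
        data, index=pd.Index([e.name for e in catalogue], name="epitope")
    )


def peptides_with_epitope(
    repertoire: Iterable[str], catalogue: Sequence[Epitope] | None = None
) -> set[str]:
    """Peptides of a repertoire carrying at least one T-cell epitope."""
    if catalogue is None:
        catalogue = load_epitope_catalogue()
    return {pep for pep in repertoire if any(e.sequence in pep for e in catalogue)}
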