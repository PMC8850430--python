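"""Cohort-level analytics over per-sample peptide repertoires.

Covers per-sample distinct-peptide counts, set-intersection (Venn/UpSet)
cardinalities, per-residue proteome coverage matrices with epitope and
Gln/Pro-density tracks, detection-frequency ranking, and the group
statistics used throughout: a Kruskal–Wallis omnibus test followed by
Dunn's pairwise z-tests with Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .immuno import Epitope, scan_epitopes
from .proteome import ProteinRecord, collapse_il

__all__ = [
    "SampleSet",
    "GroupComparison",
    "count_table",
    "set_intersections",
    "coverage_matrix",
    "qp_density",
    "frequency_ranking",
    "dunn_test",
    "group_compare",
]


@dataclass(frozen=True)
class SampleSet:
    """Sample→group labels plus sample→repertoire (distinct peptide keys)."""

    groups: Mapping[str, str]
    repertoires: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        missing = set(self.repertoires) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    def samples(self) -> list[str]:
        return sorted(self.groups)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.groups.values():
            if s not in seen:
                seen.append(s)
        return seen

    def union_repertoire(self, group: str) -> frozenset[str]:
        out: set[str] = set()
        for sample, g in self.groups.items():
            if g == group:
                out |= self.repertoires.get(sample, frozenset())
        return frozenset(out)


def count_table(s: SampleSet) -> pd.DataFrame:
    """Per-sample distinct-peptide counts with group labels and medians."""
    if not s.groups:
        raise ValueError("empty sample set")
    rows = [
        {"sample": sample, "group": s.groups[sample],
         "n_peptides": len(s.repertoires.get(sample, frozenset()))}
        for sample in s.samples()
    ]
    df = pd.DataFrame(rows)
    df["group_median"] = df.groupby("group")["n_peptides"].transform("median")
    return df


def set_intersections(groups: Mapping[str, Iterable[str]]) -> dict[frozenset[str], int]:
    """Cardinality of every region of the set partition over >= 2 groups.

    Keys are frozensets of group labels naming the exact membership region
    (e.g. ``{"CeD"}`` is the CeD-exclusive region, ``{"CeD","GI","HC"}``
    the triple-shared one). Regions partition the overall union.
    """
    sets = {g: set(v) for g, v in groups.items()}
    if len(sets) < 2:
        raise ValueError("need at least two groups")
    labels = sorted(sets)
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for members in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[g] for g in members))
            outside = set.union(*(sets[g] for g in labels if g not in members), set())
            regions[frozenset(members)] = len(inside - outside)
    return regions


def qp_density(sequence: str, window: int = 9) -> np.ndarray:
    """Sliding-window fraction of residues that are Q or P (centered window,
    truncated at the edges)."""
    is_qp = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_qp = ((is_qp == ord("Q")) | (is_qp == ord("P"))).astype(float)
    half = window // 2
    out = np.empty(len(sequence))
    for i in range(len(sequence)):
        lo, hi = max(0, i - half), min(len(sequence), i + half + 1)
        out[i] = is_qp[lo:hi].mean()
    return out


def coverage_matrix(
    protein: ProteinRecord,
    s: SampleSet,
    catalogue: Sequence[Epitope] | None = None,
    qp_window: int = 9,
) -> dict:
    """Per-residue detection indicators and group frequencies for one protein.

    A residue is covered in a sample iff some repertoire peptide maps to the
    protein (I/L-equivalent) spanning that residue. Group frequency is the
    fraction of the group's samples covering the residue. Companion tracks:
    epitope start positions on the protein and Q/P density.
    """
    L = len(protein.sequence)
    subject = collapse_il(protein.sequence)
    sample_rows: dict[str, np.ndarray] = {}
    for sample in s.samples():
        row = np.zeros(L)
        for pep in s.repertoires.get(sample, frozenset()):
            query = collapse_il(pep.removeprefix("pyr-"))
            start = subject.find(query)
            while start != -1:
                row[start:start + len(query)] = 1.0
                start = subject.find(query, start + 1)
        sample_rows[sample] = row
    group_rows = {
        g: np.mean([sample_rows[x] for x in s.samples() if s.groups[x] == g], axis=0)
        for g in s.group_labels()
    }
    epitope_track = np.zeros(L)
    for _, seq, start in scan_epitopes(protein.sequence, catalogue):
        epitope_track[start - 1:start - 1 + len(seq)] = 1.0
    return {
        "accession": protein.accession,
        "length": L,
        "samples": sample_rows,
        "groups": group_rows,
        "epitope_track": epitope_track,
        "qp_density": qp_density(protein.sequence, qp_window),
    }


def coverage_frame(cov: dict) -> pd.DataFrame:
    """Flatten a coverage matrix into a residue-indexed DataFrame for export."""
    data: dict[str, np.ndarray] = {}
    for sample, row in cov["samples"].items():
        data[f"sample:{sample}"] = row
    for group, row in cov["groups"].items():
        data[f"group:{group}"] = row
    data["epitope_track"] = cov["epitope_track"]
    data["qp_density"] = cov["qp_density"]
    return pd.DataFrame(data, index=pd.RangeIndex(1, cov["length"] + 1, name="residue"))


def frequency_ranking(sample_repertoires: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Peptides ranked by the number of samples containing them.

    Descending count, ties broken lexicographically — deterministic under
    sample reordering.
    """
    counts: dict[str, int] = {}
    for repertoire in sample_repertoires.values():
        for pep in set(repertoire):
            counts[pep] = counts.get(pep, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["peptide", "n_samples"])


@dataclass(frozen=True)
class GroupComparison:
    statistic: float  # Kruskal–Wallis H (tie-corrected)
    pvalue: float
    medians: dict
    pairwise: pd.DataFrame | None  # columns: group1, group2, z, p, p_adj


def dunn_test(values: Sequence[float], labels: Sequence[str]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks, Bonferroni-adjusted.

    z = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − T] (1/n_i + 1/n_j)), with the tie
    term T = Σ(t³−t) / (12(N−1)); two-sided p, Bonferroni over all pairs.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    groups = sorted(set(labels.tolist()))
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    n = {g: int((labels == g).sum()) for g in groups}
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / n[g1] + 1.0 / n[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df


def group_compare(counts: Mapping[str, float], groups: Mapping[str, str]) -> GroupComparison:
    """Kruskal–Wallis omnibus over per-sample statistics, then Dunn pairwise.

    ``counts`` maps sample id to its statistic (e.g. wheat-peptide count);
    ``groups`` maps sample id to group label. Each group needs >= 2 samples.
    """
    labels = sorted(set(groups[s] for s in counts))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    by_group = {g: [counts[s] for s in counts if groups[s] == g] for g in labels}
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("each group needs at least two samples")
    medians = {g: float(np.median(v)) for g, v in by_group.items()}
    all_values = [v for g in labels for v in by_group[g]]
    if len(set(all_values)) == 1:
        # all observations identical: H = 0 by convention, no evidence
        n_pairs = len(labels) * (len(labels) - 1) // 2
        pairwise = pd.DataFrame(
            [{"group1": a, "group2": b, "z": 0.0, "p": 1.0, "p_adj": 1.0}
             for a, b in itertools.combinations(labels, 2)]
        )
        return GroupComparison(0.0, 1.0, medians, pairwise)
    H, p = stats.kruskal(*(by_group[g] for g in labels))
    value_list = [v for g in labels for v in by_group[g]]
    label_list = [g for g in labels for _ in by_group[g]]
    pairwise = dunn_test(value_list, label_list)
    return GroupComparison(float(H), float(p), medians, pairwise)
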