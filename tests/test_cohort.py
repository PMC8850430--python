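"""Cohort analytics: counts, set regions, coverage, ranking, group statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from urinopept.cohort import (
    SampleSet,
    count_table,
    coverage_matrix,
    dunn_test,
    frequency_ranking,
    group_compare,
    qp_density,
    set_intersections,
)
from urinopept.proteome import ProteinRecord


def make_sampleset(reps: dict[str, set], groups: dict[str, str]) -> SampleSet:
    return SampleSet(groups, {k: frozenset(v) for k, v in reps.items()})


class TestCountTable:
    def test_counts_and_median(self):
        s = make_sampleset(
            {"a": set(), "b": set("x" * 1), "c": {"x", "y"}},
            {"a": "G", "b": "G", "c": "G"},
        )
        df = count_table(s).set_index("sample")
        assert df.loc["a", "n_peptides"] == 0
        assert df.loc["c", "n_peptides"] == 2
        assert df["group_median"].unique().tolist() == [1.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_table(make_sampleset({}, {}))


class TestSetIntersections:
    def test_two_group_regions(self):
        regions = set_intersections({"A": {"x", "y"}, "B": {"y", "z"}})
        assert regions[frozenset({"A"})] == 1
        assert regions[frozenset({"B"})] == 1
        assert regions[frozenset({"A", "B"})] == 1

    def test_disjoint_sets(self):
        regions = set_intersections({"w": {"a"}, "b": {"b"}, "r": {"c"}})
        assert all(v == 0 for k, v in regions.items() if len(k) > 1)

    @given(
        st.dictionaries(
            st.sampled_from(["A", "B", "C"]),
            st.sets(st.integers(0, 30), max_size=15),
            min_size=2,
            max_size=3,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_regions_partition_the_union(self, groups):
        regions = set_intersections(groups)
        union = set().union(*groups.values())
        assert sum(regions.values()) == len(union)


class TestCoverage:
    PROT = ProteinRecord("P1", "test protein", "AAQQPQQAAA")

    def test_single_peptide_indicator_row(self):
        s = make_sampleset({"s1": {"QQPQQ"}}, {"s1": "G"})
        cov = coverage_matrix(self.PROT, s)
        assert cov["samples"]["s1"].tolist() == [0, 0, 1, 1, 1, 1, 1, 0, 0, 0]

    def test_group_frequency_is_mean_of_indicators(self):
        rng = np.random.default_rng(5)
        protein = ProteinRecord("P2", "d", "".join(rng.choice(list("QPFLSA"), size=60)))
        reps = {}
        for i in range(6):
            start = int(rng.integers(0, 50))
            reps[f"s{i}"] = {protein.sequence[start:start + 8]}
        s = make_sampleset(reps, {k: "G" for k in reps})
        cov = coverage_matrix(protein, s)
        manual = np.mean([cov["samples"][k] for k in reps], axis=0)
        assert np.allclose(cov["groups"]["G"], manual)

    def test_duplicate_peptides_do_not_change_frequency(self):
        s1 = make_sampleset({"s1": {"QQPQQ"}}, {"s1": "G"})
        cov1 = coverage_matrix(self.PROT, s1)
        # the same residues covered through two overlapping peptides
        s2 = make_sampleset({"s1": {"QQPQQ", "AQQPQQ"}}, {"s1": "G"})
        cov2 = coverage_matrix(self.PROT, s2)
        assert (cov2["groups"]["G"] >= cov1["groups"]["G"]).all()

    def test_qp_density_uniform(self):
        assert np.allclose(qp_density("QPQPQPQPQ", window=9), 1.0)

    def test_qp_density_window_edges(self):
        d = qp_density("QQQQAAAAA", window=3)
        assert d[0] == 1.0 and d[-1] == 0.0


class TestFrequencyRanking:
    def test_descending_then_lexicographic(self):
        reps = {"s1": {"B", "A"}, "s2": {"B"}, "s3": {"B", "C"}}
        df = frequency_ranking(reps)
        assert df["peptide"].tolist() == ["B", "A", "C"]
        assert df["n_samples"].tolist() == [3, 1, 1]

    def test_invariant_to_sample_order(self):
        reps = {"s1": {"X", "Y"}, "s2": {"Y"}}
        a = frequency_ranking(reps)
        b = frequency_ranking(dict(reversed(list(reps.items()))))
        assert a.equals(b)


def kruskal_closed_form(groups: list[list[float]]) -> float:
    """Textbook tie-corrected rank statistic, independent of scipy.

    H = [12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2] / [1 - sum(t^3-t)/(N^3-N)]
    """
    flat = [v for g in groups for v in g]
    N = len(flat)
    order = sorted(range(N), key=lambda i: flat[i])
    ranks = [0.0] * N
    i = 0
    while i < N:
        j = i
        while j + 1 < N and flat[order[j + 1]] == flat[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    H = 0.0
    pos = 0
    for g in groups:
        n = len(g)
        rbar = sum(ranks[pos:pos + n]) / n
        H += n * (rbar - (N + 1) / 2) ** 2
        pos += n
    H *= 12.0 / (N * (N + 1))
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - float((counts**3 - counts).sum()) / (N**3 - N)
    return H / tie if tie > 0 else float("nan")


class TestGroupCompare:
    def test_identical_distributions_null(self):
        counts = {f"s{i}": 5.0 for i in range(6)}
        groups = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        cmp = group_compare(counts, groups)
        assert cmp.statistic == 0.0
        assert (cmp.pairwise["p_adj"] >= 0.9).all()

    def test_hand_computed_two_groups(self):
        """{1,2,3} vs {4,5,6}: rank sums 6 and 15, H = 12/42*(2*1.5^2*... )"""
        counts = dict(zip("abcdef", [1, 2, 3, 4, 5, 6]))
        groups = dict(zip("abcdef", "AAABBB"))
        cmp = group_compare(counts, groups)
        assert cmp.statistic == pytest.approx(kruskal_closed_form([[1, 2, 3], [4, 5, 6]]), abs=1e-12)
        assert cmp.statistic == pytest.approx(3.857142857, abs=1e-6)

    def test_exhaustive_small_cases_match_closed_form(self):
        """All <=6-observation inputs over a bounded value alphabet, with and
        without ties, across 2- and 3-group layouts."""
        layouts = [(2, 2), (2, 3), (3, 3), (2, 2, 2)]
        for layout in layouts:
            n = sum(layout)
            for values in itertools.product((0, 1, 2), repeat=n):
                if len(set(values)) == 1:
                    continue  # degenerate: scipy raises, handled separately
                groups = []
                pos = 0
                for size in layout:
                    groups.append(list(values[pos:pos + size]))
                    pos += size
                expected = kruskal_closed_form(groups)
                got, _ = sps.kruskal(*groups)
                assert got == pytest.approx(expected, abs=1e-10), (layout, values)

    def test_dunn_symmetry_and_bounds(self):
        counts = dict(zip("abcdefgh", [1, 2, 3, 10, 11, 12, 5, 6]))
        groups = dict(zip("abcdefgh", "AAABBBCC"))
        cmp = group_compare(counts, groups)
        df = cmp.pairwise
        assert ((df["p_adj"] >= 0) & (df["p_adj"] <= 1)).all()
        assert len(df) == 3
        # z antisymmetry under group swap
        z_ab = df[(df.group1 == "A") & (df.group2 == "B")]["z"].iloc[0]
        flipped = dunn_test([1, 2, 3, 10, 11, 12, 5, 6], list("BBBAAACC"))
        z_ba = flipped[(flipped.group1 == "A") & (flipped.group2 == "B")]["z"].iloc[0]
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            group_compare({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": "A", "b": "A", "c": "B"})
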