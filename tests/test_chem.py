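"""Peptide chemistry: parsing, masses, compositions, isotope envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urinopept.chem import (
    ElementalComposition,
    MODIFICATIONS,
    Peptide,
    PeptideParseError,
    elemental_composition,
    format_modified_sequence,
    isotope_envelope,
    monoisotopic_mass,
    mz,
    parse_modified_sequence,
    peptide_envelope,
)

from conftest import brute_force_envelope

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=30)


class TestParsing:
    def test_fixed_carbamidomethyl_policy(self):
        p = parse_modified_sequence("SCHVMQQQCC")
        assert len(p) == 10
        assert p.mods == ((2, "carbamidomethyl"), (9, "carbamidomethyl"), (10, "carbamidomethyl"))

    def test_bare_sequence_without_policy(self):
        p = parse_modified_sequence("GQQQPFPPQQPYPQPQPFPS", fixed_carbamidomethyl=False)
        assert p.mods == ()

    def test_pyroglutamate_annotation(self):
        p = parse_modified_sequence("Q(-17.03)TFPHQPQQQVPQPQQPQQP")
        assert p.mods == ((1, "pyroglutamate_from_Q"),)

    @pytest.mark.parametrize("bad", ["", "AX(+57.02)B", "Q(-99.0)A", "A(+57.02", "C(+3.00)"])
    def test_parse_errors(self, bad):
        with pytest.raises(PeptideParseError):
            parse_modified_sequence(bad)

    @given(sequences)
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_is_identity(self, seq):
        p = parse_modified_sequence(seq)
        assert parse_modified_sequence(format_modified_sequence(p)) == p

    def test_invariant_pyroglu_excludes_deamidation_at_1(self):
        with pytest.raises(ValueError):
            Peptide("QQP", ((1, "pyroglutamate_from_Q"), (1, "deamidation")))

    def test_mod_residue_restrictions(self):
        with pytest.raises(ValueError):
            Peptide("AAA", ((2, "oxidation"),))
        with pytest.raises(ValueError):
            Peptide("AQA", ((2, "pyroglutamate_from_Q"),))  # not N-terminal


class TestMass:
    def test_reference_masses_reproduce(self, reference_catalogue):
        """Every printed peptide mass reproduces within ±0.0005 Da given its
        footnoted modifications (fixed Cys carbamidomethylation implied)."""
        for _, row in reference_catalogue.iterrows():
            mods = []
            if isinstance(row["mods"], str) and row["mods"]:
                for item in row["mods"].split(";"):
                    pos, kind = item.split(":")
                    mods.append((int(pos), kind))
            p = parse_modified_sequence(row["sequence"])
            p = Peptide(p.sequence, tuple(sorted(p.mods + tuple(mods))))
            assert monoisotopic_mass(p) == pytest.approx(row["mass_da"], abs=5e-4), row[
                "display_sequence"
            ]

    def test_glycine(self):
        assert monoisotopic_mass(Peptide("G")) == pytest.approx(75.03203, abs=1e-4)

    def test_mz_arithmetic(self):
        assert mz(2292.0962, 2) == pytest.approx(1147.0554, abs=1e-3)
        assert mz(2292.0962, 3) == pytest.approx(765.0393, abs=1e-3)
        assert mz(1000.0, 1) == pytest.approx(1001.007276, abs=1e-6)
        with pytest.raises(ValueError):
            mz(1000.0, 0)

    @given(sequences, sequences)
    @settings(max_examples=100, deadline=None)
    def test_mass_additivity_under_concatenation(self, a, b):
        """Condensation removes one water: m(AB) = m(A) + m(B) - m(H2O)."""
        pa, pb, pab = Peptide(a), Peptide(b), Peptide(a + b)
        assert monoisotopic_mass(pab) == pytest.approx(
            monoisotopic_mass(pa) + monoisotopic_mass(pb) - 18.010565, abs=1e-9
        )

    def test_agreement_with_pyteomics(self):
        """Independent mass cross-check on unmodified sequences."""
        pmass = pytest.importorskip("pyteomics.mass")
        for seq in ("GQQQPFPPQQPYPQPQPFPS", "SCHVMQQQCC", "ACDEFGHIKLMNPQRSTVWY"):
            ours = monoisotopic_mass(Peptide(seq))
            theirs = pmass.calculate_mass(sequence=seq)
            assert ours == pytest.approx(theirs, abs=1e-4)


class TestComposition:
    def test_free_glycine(self):
        assert elemental_composition(Peptide("G")).as_dict() == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_condensation_removes_water(self):
        assert elemental_composition(Peptide("GG")).as_dict() == {"C": 4, "H": 8, "N": 2, "O": 3}

    def test_deamidation_formula_change(self):
        native = elemental_composition(Peptide("AQA"))
        deam = elemental_composition(Peptide("AQA", ((2, "deamidation"),)))
        delta = deam - native
        assert delta.as_dict() == {"H": -1, "N": -1, "O": 1}
        assert delta.mass() == pytest.approx(0.984016, abs=1e-5)

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_composition_mass_matches_sequence_mass(self, seq):
        p = Peptide(seq)
        assert elemental_composition(p).mass() == pytest.approx(
            monoisotopic_mass(p), abs=1e-6
        )

    def test_modification_deltas_self_consistent(self):
        """Each modification's mass equals the mass of its formula change."""
        expected = {
            "carbamidomethyl": 57.021464,
            "oxidation": 15.994915,
            "pyroglutamate_from_Q": -17.026549,
            "pyroglutamate_from_E": -18.010565,
            "deamidation": 0.984016,
        }
        for name, val in expected.items():
            assert MODIFICATIONS[name].delta_mass == pytest.approx(val, abs=1e-6)


class TestEnvelope:
    def test_single_carbon(self):
        env = isotope_envelope(ElementalComposition.from_dict({"C": 1}))
        assert env.peaks[0][0] == pytest.approx(12.0, abs=1e-6)
        assert env.peaks[0][1] == pytest.approx(0.9893, abs=1e-4)
        assert env.peaks[1][1] == pytest.approx(0.0107, abs=1e-4)

    @pytest.mark.parametrize(
        "formula",
        [
            {"H": 2, "O": 1},
            {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
            {"S": 3},
            {"C": 20, "H": 30, "N": 5, "O": 4},
        ],
    )
    def test_matches_exhaustive_enumeration(self, formula):
        oracle = brute_force_envelope(formula)
        env = isotope_envelope(ElementalComposition.from_dict(formula), prune_threshold=0.0,
                               max_peaks=25)
        mono = env.peaks[0][0]
        for m, abundance in env.peaks:
            k = round(m - mono)
            assert abundance == pytest.approx(oracle.get(k, 0.0), abs=1e-9)

    @given(
        st.fixed_dictionaries(
            {},
            optional={
                "C": st.integers(1, 25),
                "H": st.integers(1, 25),
                "N": st.integers(0, 5),
                "O": st.integers(0, 5),
                "S": st.integers(0, 2),
            },
        ).filter(lambda d: 0 < sum(d.values()) <= 60)
    )
    @settings(max_examples=25, deadline=None)
    def test_random_compositions_match_enumeration(self, formula):
        oracle = brute_force_envelope(formula)
        env = isotope_envelope(ElementalComposition.from_dict(formula), prune_threshold=0.0,
                               max_peaks=25)
        mono = env.peaks[0][0]
        for m, abundance in env.peaks:
            k = round(m - mono)
            assert abundance == pytest.approx(oracle.get(k, 0.0), abs=1e-9)

    def test_peptide_envelope_structure(self):
        """Peak spacing near one neutron; at ~2.3 kDa the M+1 peak already
        exceeds the monoisotopic peak (the source of deamidation artifacts)."""
        env = peptide_envelope(Peptide("GQQQPFPPQQPYPQPQPFPS"))
        spacings = np.diff([m for m, _ in env.peaks])
        assert ((spacings >= 1.0020) & (spacings <= 1.0045)).all()
        assert env.peaks[1][1] > env.peaks[0][1]
        assert env.monoisotopic_mass == pytest.approx(2292.0962, abs=5e-4)

    def test_abundances_sum_to_one_before_pruning(self):
        env = peptide_envelope(Peptide("SCHVMQQQCC"), prune_threshold=0.0, max_peaks=40)
        assert sum(a for _, a in env.peaks) == pytest.approx(1.0, abs=1e-9)

    def test_prune_and_renormalize(self):
        comp = ElementalComposition.from_dict({"C": 10, "H": 20})
        raw = isotope_envelope(comp, prune_threshold=1e-4, max_peaks=3)
        norm = isotope_envelope(comp, prune_threshold=1e-4, max_peaks=3, renormalize=True)
        assert sum(a for _, a in norm.peaks) == pytest.approx(1.0, abs=1e-12)
        assert len(raw.peaks) <= 3
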