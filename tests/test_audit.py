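"""Deamidation-artifact adjudication: rules, fragments, parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urinopept._constants import C13_DELTA, PROTON_MASS
from urinopept.audit import (
    AuditConfig,
    PrecursorObservation,
    SpectrumPeakList,
    adjudicate,
    adjudicate_ms1,
    site_determining_ions,
    theoretical_pair,
)
from urinopept.chem import Peptide, monoisotopic_mass, mz


def flagged(seq: str, site: int) -> Peptide:
    return Peptide(seq, ((site, "deamidation"),))


class TestTheoreticalPair:
    def test_single_deamidation_gap(self):
        (nm, _), (dm, _) = theoretical_pair(flagged("GQQQPFPPQQPYPQPQPFPS", 2))
        assert dm - nm == pytest.approx(0.984016, abs=1e-5)

    def test_isotope_ambiguity_constant(self):
        """The deamidated monoisotopic mass sits 0.0193 Da from the native
        peptide's one-13C peak — the root cause of the artifact."""
        (nm, _), (dm, _) = theoretical_pair(flagged("GQQQPFPPQQPYPQPQPFPS", 2))
        assert (nm + C13_DELTA) - dm == pytest.approx(0.019339, abs=1e-5)

    def test_two_deamidations_linear(self):
        p = Peptide("AQAQA", ((2, "deamidation"), (4, "deamidation")))
        (nm, _), (dm, _) = theoretical_pair(p)
        assert dm - nm == pytest.approx(2 * 0.984016, abs=1e-5)

    def test_requires_deamidation(self):
        with pytest.raises(ValueError):
            theoretical_pair(Peptide("AQA"))


class TestMs1Rules:
    SEQ = "GQQQPFPPQQPYPQPQPFPS"

    def _obs(self, neutral: float, charge: int = 2) -> PrecursorObservation:
        return PrecursorObservation(mz(neutral, charge), charge)

    def test_rule2_reassigns_when_closer_to_native_isotope(self):
        p = flagged(self.SEQ, 2)
        (nm, _), _ = theoretical_pair(p)
        res = adjudicate_ms1(p, self._obs(nm + C13_DELTA), None)
        assert res.verdict == "NATIVE_REASSIGNED"
        assert res.rule_fired == "closer_to_native_isotope"
        assert res.evidence["native_distance_da"] == pytest.approx(0.0, abs=1e-9)
        assert res.evidence["deamidated_distance_da"] == pytest.approx(0.019339, abs=1e-5)

    def test_rule1_requires_native_mono_peak(self):
        p = flagged(self.SEQ, 2)
        (nm, ne), _ = theoretical_pair(p)
        ms1 = SpectrumPeakList("MS1", tuple(sorted(ne.mz_peaks(2))))
        res = adjudicate_ms1(p, self._obs(nm + C13_DELTA), ms1)
        assert res.verdict == "NATIVE_REASSIGNED"
        assert res.rule_fired == "monoisotopic_native_visible"

    def test_exact_deamidated_mass_defers_to_ms2(self):
        p = flagged(self.SEQ, 2)
        _, (dm, de) = theoretical_pair(p)
        ms1 = SpectrumPeakList("MS1", tuple(sorted(de.mz_peaks(2))))
        res = adjudicate_ms1(p, self._obs(dm), ms1)
        assert res.verdict == "AMBIGUOUS_EXCLUDED"
        assert res.rule_fired == "ms2_inconclusive"

    def test_unflagged_peptide_not_audited(self):
        res = adjudicate_ms1(Peptide("QQPQQ"), PrecursorObservation(500.0, 2), None)
        assert res.verdict == "NATIVE_UNFLAGGED"

    @pytest.mark.parametrize("charge", [2, 3, 4, 5])
    def test_charge_invariance(self, charge):
        """The decision depends only on neutral mass, not on the charge the
        same species was observed at."""
        p = flagged(self.SEQ, 2)
        (nm, _), _ = theoretical_pair(p)
        res = adjudicate_ms1(p, self._obs(nm + 2 * C13_DELTA, charge), None)
        assert res.verdict == "NATIVE_REASSIGNED"
        assert res.evidence["native_isotope_index"] == 2

    def test_widening_tolerance_never_flips_native_to_deamidated(self):
        p = flagged(self.SEQ, 2)
        (nm, _), _ = theoretical_pair(p)
        obs = self._obs(nm + C13_DELTA + 0.004)
        verdicts = []
        for ppm in (5.0, 10.0, 20.0, 50.0):
            res = adjudicate(p, obs, None, None, AuditConfig(precursor_tol_ppm=ppm))
            verdicts.append(res.verdict)
        assert "DEAMIDATED_CONFIRMED" not in verdicts
        assert verdicts[1] == "NATIVE_REASSIGNED"


class TestSiteDeterminingIons:
    def test_small_peptide_b_series(self):
        native, deam = site_determining_ions(Peptide("QQP"), 1, "b")
        # b1 and b2 cover site 1; b3 (full length) is not a fragment
        assert len(native) == 2
        for n, d in zip(native, deam):
            assert d - n == pytest.approx(0.984016, abs=1e-6)

    def test_last_residue_site(self):
        native_b, _ = site_determining_ions(Peptide("QPQ"), 3, "b")
        assert native_b == ()  # only the full-length prefix covers site 3
        native_y, deam_y = site_determining_ions(Peptide("QPQ"), 3, "y")
        assert len(native_y) == 2  # y1 and y2
        assert deam_y[0] - native_y[0] == pytest.approx(0.984016, abs=1e-6)

    def test_pyroglutamate_site_conflict(self):
        p = Peptide("QQP", ((1, "pyroglutamate_from_Q"),))
        with pytest.raises(ValueError):
            site_determining_ions(p, 1, "b")

    def test_non_nq_site_rejected(self):
        with pytest.raises(ValueError):
            site_determining_ions(Peptide("APQ"), 1, "b")

    def test_cz_series_offsets(self):
        nb, _ = site_determining_ions(Peptide("QAP"), 1, "b")
        nc, _ = site_determining_ions(Peptide("QAP"), 1, "c")
        assert nc[0] - nb[0] == pytest.approx(17.026549, abs=1e-5)


class TestFullAdjudication:
    def test_ms2_site_confirmation(self):
        """Deferred MS1 plus uniquely localizing shifted fragments confirms
        deamidation at exactly one site."""
        p = flagged("AQPQA", 2)
        _, (dm, _) = theoretical_pair(p)
        obs = PrecursorObservation(mz(dm, 2), 2)
        _, deam_b = site_determining_ions(p, 2, "b")
        _, deam_y = site_determining_ions(p, 2, "y")
        ms2 = SpectrumPeakList("MS2", tuple(sorted([(deam_b[0], 1e5), (deam_y[0], 1e5)])))
        res = adjudicate(p, obs, None, ms2)
        assert res.verdict == "DEAMIDATED_CONFIRMED"
        assert res.rule_fired == "ms2_site_confirmed"
        assert res.evidence["site"] == 2

    def test_absent_ms2_excludes(self):
        p = flagged("AQPQA", 2)
        _, (dm, _) = theoretical_pair(p)
        res = adjudicate(p, PrecursorObservation(mz(dm, 2), 2), None, None)
        assert res.verdict == "AMBIGUOUS_EXCLUDED"

    def test_nonlocalizing_ms2_excludes(self):
        """Shifted ions covering several Gln sites equally cannot localize
        the deamidation and the record is excluded."""
        p = flagged("AQPQA", 2)
        _, (dm, _) = theoretical_pair(p)
        # a long shifted b-ion covers both Gln sites
        _, deam_b = site_determining_ions(p, 4, "b")
        ms2 = SpectrumPeakList("MS2", ((deam_b[0], 1e5),))
        res = adjudicate(p, PrecursorObservation(mz(dm, 2), 2), None, ms2)
        assert res.verdict == "AMBIGUOUS_EXCLUDED"


class TestParameterRecovery:
    @pytest.mark.parametrize("rho", [0.5, 0.9, 1.0])
    def test_planted_artifact_rate_recovered(self, rho):
        """The NATIVE_REASSIGNED fraction among flagged records recovers the
        planted artifact rate within its 95% binomial interval."""
        from urinopept.assign import IdentificationRecord
        from urinopept.io import audit_records
        from urinopept.synth import SynthConfig, simulate_cohort

        cfg = SynthConfig(seed=202, artifact_fraction=rho)
        cohort = simulate_cohort(cfg)
        records = [
            IdentificationRecord.from_text(
                r.sample, r.sequence, r.mz, int(r.z),
                replicate=str(r.replicate), spectrum_id=r.spectrum_id,
            )
            for r in cohort.identifications.itertuples()
        ]
        spectra = {}
        for (sid, lvl), sub in cohort.peaks.groupby(["spectrum_id", "level"]):
            sub = sub.sort_values("mz")
            spectra[(sid, lvl)] = SpectrumPeakList(lvl, tuple(zip(sub.mz, sub.intensity)))
        df = audit_records(records, spectra)
        fl = df[df["verdict"] != "NATIVE_UNFLAGGED"]
        n = len(fl)
        assert n > 30
        rho_hat = (fl["verdict"] == "NATIVE_REASSIGNED").mean()
        half_width = 1.96 * np.sqrt(max(rho * (1 - rho), 0.25 / n) / n)
        assert abs(rho_hat - rho) <= half_width + 0.02
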