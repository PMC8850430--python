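"""Adjudicating a deamidation assignment from MS1 evidence.

A native peptide whose one-13C isotope peak was selected for fragmentation
is only 0.0193 Da away from the deamidated monoisotopic mass — search
engines routinely mistake one for the other. The audit compares the
observed precursor against both theoretical forms.
"""

from urinopept import Peptide, adjudicate, mz, theoretical_pair
from urinopept.audit import PrecursorObservation
from urinopept._constants import C13_DELTA

# the engine reported this peptide as deamidated at Gln-2
flagged = Peptide("GQQQPFPPQQPYPQPQPFPS", ((2, "deamidation"),))
(native_mass, native_env), (deam_mass, deam_env) = theoretical_pair(flagged)

print(f"native monoisotopic     : {native_mass:10.4f} Da")
print(f"deamidated monoisotopic : {deam_mass:10.4f} Da  (+{deam_mass-native_mass:.4f})")
print(f"native + one 13C        : {native_mass + C13_DELTA:10.4f} Da "
      f"(only {native_mass + C13_DELTA - deam_mass:+.4f} from deamidated)")

# the instrument actually fragmented the native M+1 peak:
obs = PrecursorObservation(mz(native_mass + C13_DELTA, 2), charge=2)
result = adjudicate(flagged, obs, ms1=None, ms2=None)
print(f"\nverdict: {result.verdict} (rule: {result.rule_fired})")
print(f"distance to nearest native isotopologue    : "
      f"{result.evidence['native_distance_da']:.4f} Da")
print(f"distance to nearest deamidated isotopologue: "
      f"{result.evidence['deamidated_distance_da']:.4f} Da")
# NATIVE_REASSIGNED: the observation sits exactly on a native isotope
# position, so the deamidation call was an artifact of isotope mispicking.
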