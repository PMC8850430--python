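"""Scanning peptides for T-cell epitopes and antibody-recognition motifs."""

from urinopept import scan_epitopes, scan_antibody_motifs
from urinopept.immuno import INNATE_20MER, innate_family

seq = "TQQPQQPFPQQPQQPFPQQPQQPFPQ"  # a gamma-gliadin repeat peptide
print(f"peptide: {seq}")
for name, epitope, start in scan_epitopes(seq):
    print(f"  T-cell epitope {name:30s} {epitope} @ {start}")

print(f"\ninnate-response 20-mer: {INNATE_20MER}")
print(f"  family({INNATE_20MER[:-1]}) = {innate_family(INNATE_20MER[:-1])}")
print(f"  antibody motifs: {scan_antibody_motifs(INNATE_20MER) or 'none (G12/A1)'}")
# The most prevalent urinary wheat peptide carries no Leu and hence no
# G12/A1 motif — commercial immunoassays targeting those motifs miss it.

print(f"\nG12 motif example: QPQLPYP -> {scan_antibody_motifs('QPQLPYP')}")
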