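"""Assigning peptides to human vs grain proteomes.

Shows the precedence rules: the immunoglobulin YVRPD motif forces a human
call even for wheat-unique mappings; human-database matches outrank grain
matches; otherwise the grain database decides.
"""

from urinopept.experiments import default_databases
from urinopept import assign_species

human_db, grain_dbs = default_databases()

peptides = [
    "GQQQPFPPQQPYPQPQPFPS",   # wheat-only alpha-gliadin peptide
    "AAYVRPDGGQQ",            # carries the Ig joining-region motif
    "WWWWWWWW",               # matches nothing
]

for seq in peptides:
    a = assign_species(seq, human_db, grain_dbs)
    print(f"{seq:24s} -> {a.species:9s} (rules: {' > '.join(a.rule_trail)})")
    for db_label, accession, offset in a.matches[:3]:
        print(f"{'':24s}    {db_label}:{accession} @ {offset}")

# "human" beats "wheat" whenever both match: endogenous peptides shared
# with grain sequences must not inflate the dietary repertoire.
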