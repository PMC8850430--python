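# Celiac-disease-relevant T-cell epitope catalogue, v1.
# 9-mer core sequences in their native (Gln) form; matched as exact substrings.
name	sequence
DQ2.5-glia-a1a	PFPQPQLPY
DQ2.5-glia-a1b	PYPQPQLPY
DQ2.5-glia-a2	PQPQLPYPQ
DQ2.5-glia-a3	FRPQQPYPQ
DQ2.5-glia-g1/DQ8.5-glia-g1/DQ8-glia-g2	PQQSFPQQQ
DQ2.5-glia-g3/DQ8-glia-g1b	QQPQQPYPQ
DQ2.5-glia-g4a	SQPQQQFPQ
DQ2.5-glia-g4b	PQPQQQFPQ
DQ2.5-glia-g4c/DQ8-glia-g1a	QQPQQPFPQ
DQ2.5-glia-g4d	PQPQQPFCQ
DQ2.5-glia-g4e	LQPQQPFPQ
DQ2.5-glia-g5	QQPFPQQPQ
DQ2.5-glia-o1/DQ2.5-hor-1/DQ2.5-sec-1	PFPQPQQPF
DQ2.5-glia-o2	PQPQQPFPW
DQ2.5-glut-L1/DQ2.2-glut-L1	PFSQQQQPV
DQ2.5-glut-L2	FSQQQQSPF
DQ8.5-glut-H1/DQ8-glut-H1	QGYYPTSPQ
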