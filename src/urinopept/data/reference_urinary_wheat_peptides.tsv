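# Reference catalogue of urinary wheat-derived peptides (printed forms).
# display_sequence: as reported, with [I/L] marking an isobaric ambiguity and
#   PyrQ an N-terminal pyroglutamate; sequence: residue letters only, with an
#   arbitrary L chosen for the [I/L] position.
# mods: semicolon list of position:kind (fixed carbamidomethylation of every
#   Cys is implied and not listed); mass_da: printed monoisotopic mass of the
#   modified peptide; bold_epitopes: semicolon list of start:epitope_sequence
#   spans highlighted in the printed catalogue (1-based).
display_sequence	sequence	mods	mass_da	proteins	n_participants	bold_epitopes
GQQQPFPPQQPYPQPQPFPS	GQQQPFPPQQPYPQPQPFPS		2292.0962	alpha/beta-gliadin; alpha-gliadin	8
GQQQPFPPQQPYPQPQPFP	GQQQPFPPQQPYPQPQPFP		2205.0642	alpha/beta-gliadin; alpha-gliadin	7
SQQPEQTISQQPQQPFPQQPHQPQQPYPQQQPYGSSL	SQQPEQTISQQPQQPFPQQPHQPQQPYPQQQPYGSSL		4284.0259	omega-gliadin	6	10:QQPQQPFPQ
SCHVMQQQCC	SCHVMQQQCC		1336.4781	gamma-gliadin; LMW glutenin	6
LGQQQPFPPQQPYPQPQPFPSQQP	LGQQQPFPPQQPYPQPQPFPSQQP		2758.3500	alpha/beta-gliadin; alpha-gliadin	5
SQQPQQPFPQQPHQPQQPYPQ	SQQPQQPFPQQPHQPQQPYPQ		2512.1882	omega-gliadin; LMW glutenin	5	2:QQPQQPFPQ
SCHVMQQQCCQ	SCHVMQQQCCQ		1464.5367	gamma-gliadin; LMW glutenin	5
PyrQTFPHQPQQQVPQPQQPQQP	QTFPHQPQQQVPQPQQPQQP	1:pyroglutamate_from_Q	2348.1296	gamma-gliadin	5
PQQPPFSQQQQQQQQQQQPPFSQQQQPVL	PQQPPFSQQQQQQQQQQQPPFSQQQQPVL		3457.6763	LMW glutenin	3	20:PFSQQQQPV
TQQPQQPFPQQPQQPFPQQPQQPFPQ	TQQPQQPFPQQPQQPFPQQPQQPFPQ		3098.4998	gamma-gliadin	3	2:QQPQQPFPQ;18:QQPQQPFPQ
TQQPQQPFPQQPQQPFPQTQQPQQPFPQ	TQQPQQPFPQQPQQPFPQTQQPQQPFPQ		3327.6060	gamma-gliadin	3	2:QQPQQPFPQ;20:QQPQQPFPQ
QPFPPQQPYPQPQPFP	QPFPPQQPYPQPQPFP		1891.9257	alpha/beta-gliadin; alpha-gliadin	2
P[I/L]QPQQPFPQQPQQPFPQPQ	PLQPQQPFPQQPQQPFPQPQ		2354.1807	omega-gliadin	2	2:LQPQQPFPQ;10:QQPQQPFPQ
FLQPQQPFPQQPQQPYPQQPQQPFPQ	FLQPQQPFPQQPQQPYPQQPQQPFPQ		3145.5410	gamma-gliadin	1	2:LQPQQPFPQ;10:QQPQQPYPQ;18:QQPQQPFPQ
CHVMQQQCCQ	CHVMQQQCCQ	4:oxidation	1393.5000	gamma-gliadin; LMW glutenin	1
PyrQQQQPPFSQQPPISQQQQPPFSQQQQPQF	QQQQPPFSQQPPISQQQQPPFSQQQQPQF	1:pyroglutamate_from_Q	3416.6174	LMW glutenin	1
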