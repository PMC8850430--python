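# Methods

## Mass chemistry

Peptide masses are computed from a single constants table: IUPAC
monoisotopic element masses and natural isotopic abundances (C, H, N, O, S
only — peptides contain nothing else), standard in-chain residue formulas
for the 20 canonical amino acids, proton 1.007276 Da and water
18.010565 Da. Residue masses are *derived* from the element table rather
than stored separately, so mass arithmetic and elemental-composition
arithmetic can never disagree (the package asserts agreement to 1e-6 Da).

Five modifications are modelled, each as a formula change:
carbamidomethyl (+C2H3NO, +57.021464 Da, Cys only; treated as *fixed* — the
parser adds it to every Cys unless disabled, mirroring iodoacetamide
derivatization during sample workup), Met oxidation (+O), deamidation
(−H −N +O, +0.984016 Da, Asn/Gln), and N-terminal pyroglutamate from Gln
(−NH3) or Glu (−H2O). Parenthesized deltas in search-export sequence
strings (`"Q(-17.03)…"`) are matched to these kinds within 0.02 Da — the
product-ion tolerance of the upstream search — with ties broken by the
smallest absolute difference.

### Isotope envelopes

Theoretical envelopes are built by convolution of per-element isotope
distributions, using exponentiation-by-squaring per element. Peaks are
aggregated by integer neutron-excess bins; each bin reports the
abundance-weighted centroid mass (first-moment arrays are convolved
alongside the abundance arrays, so centroids are exact for the binning).
Defaults: prune threshold 1e-10, 10 peaks — ample for peptides ≤ 5 kDa.
Equivalence with exhaustive isotopologue enumeration is maintained to
1e-9 absolute abundance (tested up to 60 atoms; the convolution itself has
no size limit within the retained window). Average masses, fine structure
and elements beyond CHNOS are out of scope. Note that for peptides above
~1.8 kDa the one-¹³C peak exceeds the monoisotopic peak in abundance —
precisely why instruments frequently select it for fragmentation.

## Deamidation-artifact adjudication

A deamidated peptide is +0.984016 Da over native; the native one-¹³C
isotopologue is +1.003355 Da. The 0.0193 Da gap is near the precursor
tolerance for large peptides (4.5 ppm at 4.3 kDa), so engine deamidation
calls on non-monoisotopic precursor picks are frequent artifacts. The
audit decides each flagged record:

* **Rule 1 (MS1)** — the spectrum shows a peak at the native monoisotopic
  m/z *and* the fragmented precursor lies on a native isotope position
  (native + j·1.003355, j ∈ [1, 3]) within 10 ppm → reassign to native.
  Both conditions are required so that a genuine deamidated species
  coexisting with its native form is not silently reassigned.
* **Rule 2 (MS1)** — otherwise, if the observed neutral mass is *strictly*
  closer to some native isotopologue (j ≥ 1) than to every deamidated
  isotopologue (i ≥ 0) → reassign. Exact ties defer to MS2
  (conservative).
* **MS2 stage** — deferred records are scanned for site-determining
  fragments: b/y/c/z ions whose mass differs between the native form and
  the form deamidated at a candidate Asn/Gln site. Peaks matching a
  shifted fragment within 0.02 Da (and not also matching the native
  fragment) count toward that site. Exactly one site with ≥ 2 supporting
  ions confirms the deamidation there; anything else — including a missing
  MS2 spectrum — excludes the record from all downstream analysis.

`min_site_ions = 2` operationalizes "multiple site-determining ions"; the
maximum mispicked isotope index is 3 (second, occasionally third peak).
Fragment matching is presence-within-tolerance only; intensities are
ignored. Isotope-pattern shape comparison is not part of the decision and
is left as a diagnostic. Because a shifted prefix ion supports every
candidate site it covers, unique localization effectively requires ions
bracketing the site from both termini — multi-Gln peptides without such
brackets are excluded, matching the stringency of manual validation.

## Databases and species assignment

Databases merge curated (SwissProt-tier) records, always kept, with
automatically annotated (TrEMBL-tier) records kept only when the
*description line* contains a storage-protein keyword (gliadin, glutenin,
secalin, hordein; case-insensitive substring). Duplicate accessions keep
the curated tier. Coordinates are 1-based inclusive in every report
(internally half-open 0-based). UniProt network retrieval is deliberately
excluded; the package operates on local FASTA only.

Lookup treats I and L as one symbol (collapsed to `L`, the reported
convention) because CID/EThcD cannot distinguish them. Peptides shorter
than 5 residues (the shortest scanned motif) are never matched.

Assignment precedence: `YVRPD`-containing peptides are human (the motif is
the immunoglobulin heavy-chain joining region and appears regardless of
diet); then any human-database match is human; then a grain match assigns
that grain; else unmatched. Multi-grain studies additionally classify by
exclusive membership; peptides mapping to more than one grain proteome are
retained in full tables but excluded from unique-count outputs, and a
peptide mapping only to wheat in a rye-challenge sample is annotated as a
possible unannotated rye sequence.

Repertoire distinctness key: native residue string, I/L-collapsed,
modifications ignored *except* N-terminal pyroglutamate, which is kept as
a distinct chemical form (it marks a differently stabilized species).
This choice is configurable; variant counting conventions differ by at
most the handful of pyroglutamate forms.

## Immunological annotation

The epitope catalogue ships as a versioned TSV of 17 nine-residue
HLA-DQ2/DQ8 T-cell epitope cores, matched as exact substrings of the
native (Gln-form) sequence, overlapping occurrences included.
Deamidation-aware (Glu-substituted) matching is off by default: no
validated deamidated peptide survives the audit under the study conditions
emulated here. Antibody motifs: R5 `QXP(W/F)P`, G12 `QPQLP(Y/F)`, A1
`QLP(Y/F)PQP`. R5 results are reported separately from G12/A1: the
prevalent `GQQQPFPPQQPYPQPQPFPS` family contains an R5-pattern match
(`QQPFP`) while carrying no G12/A1 motif, and the package reports both
facts rather than asserting either as an invariant. Innate-family
classification calls a sequence a truncation/extension *variant* of the
20-mer when they share a contiguous overlap of ≥ 15 residues (the
threshold is configurable; the cutoff separates "slightly longer or
shorter versions" from short incidental fragments).

## Cohort statistics

Group comparison is a tie-corrected Kruskal–Wallis omnibus (scipy)
followed by Dunn's pairwise z-tests on pooled ranks with Bonferroni
correction over the pairs (two-sided). The Dunn step is implemented
in-package (standard formula with the Σ(t³−t)/(12(N−1)) tie term); an
all-identical-values data set short-circuits to H = 0 with p = 1.
Q/P-density tracks use a 9-residue centered window, truncated at edges.
Coverage heatmaps are numeric matrices (TSV); rendering is cosmetic and
never part of any check.

## Synthetic studies

The generator emulates the emulated study's *data level* only:

* **Toy proteomes** — Q/P-rich synthetic wheat proteins with the 16
  reference catalogue peptides embedded verbatim ([I/L] resolved to L);
  human proteins of typical composition, one carrying `YVRPD`;
  hordein-like and secalin-like proteins for barley/rye. All records are
  labelled synthetic (`SYN*` accessions).
* **Unspecific digestion** — uniform substring sampling (length 8–40) from
  the Q/P-rich proteins; because the source proteins are Q/P-rich, sampled
  peptides match the composition of real gluten digests without an extra
  biasing weight.
* **Cohort design** — groups CeD/GI/HC of 6/5/8 samples; per-sample
  distinct-peptide counts are negative binomial with control mean 24 and
  dispersion 8 (the dispersion is a free parameter — per-sample count
  spread is documented nowhere — chosen to give the wide inter-individual
  variation seen in practice); the CeD mean is 5× the control mean, drawn
  from a proportionally enlarged candidate pool so the extra diversity is
  largely CeD-exclusive sequences.
* **Deamidation channel** — 10% of records are flagged deamidated; 90% of
  those are artifacts (true native, precursor set to native + j·1.003355
  with j = 1/2/3 at probabilities 0.90/0.09/0.01, MS1 showing the native
  envelope with the monoisotopic peak suppressed 30% of the time), the
  rest genuine (precursor at the deamidated monoisotopic mass, MS1 showing
  the deamidated envelope, MS2 carrying the minimal bracketing shifted-ion
  pair that uniquely localizes the site).
* **Noise** — precursor m/z jitter is Gaussian with σ = 1 ppm, the
  high-resolution Orbitrap regime this workflow assumes (the MS1
  adjudication of a 0.0193 Da gap on multi-kDa peptides is only possible
  with ~1 ppm-scale accuracy). Peak intensities get multiplicative
  log-normal noise (σ = 0.2); the audit ignores intensities, so this only
  exercises I/O. False identifications (random non-proteome sequences)
  occur at 1%. Two replicate injections per sample, each peptide detected
  per replicate with probability 0.8 (at least one forced), aggregated by
  union downstream.

Everything derives from one integer seed; identical seeds give
byte-identical files. What the generator does **not** model: retention
time, chromatography, charge-state envelopes, instrument duty cycles, real
digestion specificity, or peptide-level abundance structure. Passing
recovery tests therefore demonstrates the *pipeline logic* — rule
correctness, statistical calibration, end-to-end bookkeeping — not
performance on real spectra.

## Validation experiments and problem sizes

The standard self-validation experiments (`urinopept.experiments`) use 200
simulated cohorts per condition (~1,600 identification records each):
artifact-rate recovery at planted rates 0.5/0.9/1.0; detection power for
the 5× diversity ratio (CeD-vs-HC Dunn-adjusted p < 0.05) and the
false-positive rate at ratio 1. The diversity experiments disable the
deamidation channel to isolate the count model; the audit is exercised by
the artifact experiments. These sizes give binomial standard errors of
~2–3 percentage points on the reported rates.

## Known limitations

* Envelope centroid masses follow the package's own binning convention and
  may differ from other calculators in the 4th decimal.
* The audit codifies mass-error evidence only; a spectrum whose isotope
  *pattern* contradicts its mass assignment is not caught.
* Keyword filtering sees description lines only; mis-annotated TrEMBL
  records pass or fail with their annotation.
* FDR control is upstream: the identification table is assumed already
  filtered (1% in the emulated design); only a score pass-through is
  provided.
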