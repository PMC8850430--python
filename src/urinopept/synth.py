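"""Synthetic urinary gluten peptidomics studies with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every pipeline stage can be exercised end-to-end without any
external data:

* toy human/wheat/barley/rye proteomes, with the reference urinary wheat
  peptide catalogue embedded verbatim in the wheat fixture and the
  immunoglobulin ``YVRPD`` motif in the human fixture;
* unspecific-digest peptide sampling (any termini, length 8–40), biased
  toward Gln/Pro-rich regions as gluten peptides are;
* a three-group cohort (6 celiac / 5 other-GI / 8 healthy) whose celiac
  samples carry ~5-fold more distinct gluten peptides;
* deamidation mis-assignment artifacts: ~10% of records are flagged as
  deamidated, and of those ~90% are in truth native peptides whose 2nd (or
  3rd) isotopic peak was picked, with MS1/MS2 peak lists constructed
  accordingly;
* search-engine-style false identifications at a 1% rate.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._constants import C13_DELTA, PROTON_MASS
from .assign import repertoire_key
from .audit import site_determining_ions
from .chem import (
    Peptide,
    elemental_composition,
    format_modified_sequence,
    isotope_envelope,
    monoisotopic_mass,
    parse_modified_sequence,
)
from .proteome import ProteinRecord, collapse_il

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SimulatedCohort",
    "make_toy_proteomes",
    "simulate_cohort",
    "write_cohort",
    "load_reference_catalogue",
]

_QP_RICH_ALPHABET = list("QPQPQPFLSYVTGAHEQP")
_PLAIN_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")


def load_reference_catalogue() -> pd.DataFrame:
    """The packaged catalogue of reference urinary wheat peptides."""
    source = resources.files("urinopept.data").joinpath(
        "reference_urinary_wheat_peptides.tsv"
    )
    with resources.as_file(source) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def _random_protein(rng: np.random.Generator, length: int, alphabet: list[str]) -> str:
    return "".join(rng.choice(alphabet, size=length))


def make_toy_proteomes(seed: int = 0) -> dict[str, list[ProteinRecord]]:
    """Deterministic toy proteomes for the four species.

    The wheat fixture contains every reference catalogue sequence as an
    exact substring (stitched into Q/P-rich synthetic storage proteins);
    one human record carries the immunoglobulin joining-region ``YVRPD``.
    All records are synthetic stand-ins, not real UniProt entries.
    """
    rng = np.random.default_rng(seed)
    cat = load_reference_catalogue()
    embedded = list(cat["sequence"])

    wheat: list[ProteinRecord] = []
    per_protein = 2
    for i in range(0, len(embedded), per_protein):
        chunk = embedded[i:i + per_protein]
        parts = [_random_protein(rng, int(rng.integers(30, 60)), _QP_RICH_ALPHABET)]
        for seq in chunk:
            parts.append(seq)
            parts.append(_random_protein(rng, int(rng.integers(30, 60)), _QP_RICH_ALPHABET))
        idx = i // per_protein + 1
        wheat.append(
            ProteinRecord(
                f"SYNW{idx:02d}_WHEAT", f"Synthetic gliadin/glutenin-like protein {idx}",
                "".join(parts), taxon="wheat",
            )
        )

    human: list[ProteinRecord] = []
    for i in range(6):
        seq = _random_protein(rng, int(rng.integers(150, 300)), _PLAIN_ALPHABET)
        if i == 0:
            mid = len(seq) // 2
            seq = seq[:mid] + "YVRPD" + seq[mid:]
        human.append(
            ProteinRecord(
                f"SYNH{i + 1:02d}_HUMAN", f"Synthetic human protein {i + 1}",
                seq, taxon="human",
            )
        )

    barley = [
        ProteinRecord(
            f"SYNB{i + 1:02d}_HORVU", f"Synthetic hordein-like protein {i + 1}",
            _random_protein(rng, int(rng.integers(150, 300)), _QP_RICH_ALPHABET),
            taxon="barley",
        )
        for i in range(4)
    ]
    rye = [
        ProteinRecord(
            f"SYNR{i + 1:02d}_SECCE", f"Synthetic secalin-like protein {i + 1}",
            _random_protein(rng, int(rng.integers(150, 300)), _QP_RICH_ALPHABET),
            taxon="rye",
        )
        for i in range(4)
    ]
    return {"human": human, "wheat": wheat, "barley": barley, "rye": rye}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the simulated cohort.

    Defaults follow the clinical design being emulated: group sizes 6/5/8,
    ~24 distinct gluten peptides per control sample, ~5-fold higher
    diversity in the celiac group, 10% of records flagged deamidated with a
    90% artifact fraction, isotope mispicks mostly at the 2nd peak, a 1%
    false-identification rate and duplicate LC–MS/MS injections.
    """

    seed: int = 0
    group_sizes: tuple[tuple[str, int], ...] = (("CeD", 6), ("GI", 5), ("HC", 8))
    mean_peptides_control: float = 24.0
    nb_dispersion: float = 8.0
    diversity_ratio: float = 5.0
    elevated_group: str = "CeD"
    length_range: tuple[int, int] = (8, 40)
    deamidation_rate: float = 0.1
    artifact_fraction: float = 0.9
    isotope_mispick_probs: tuple[float, ...] = (0.90, 0.09, 0.01)
    suppress_monoisotopic_prob: float = 0.3
    false_id_rate: float = 0.01
    mz_noise_ppm: float = 1.0
    replicates: int = 2
    replicate_detect_prob: float = 0.8
    pool_factor: float = 3.0
    include_spectra: bool = True
    proteome_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deamidation_rate", "artifact_fraction", "false_id_rate",
                     "replicate_detect_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.isotope_mispick_probs) - 1.0) > 1e-9:
            raise ValueError("isotope_mispick_probs must sum to 1")


@dataclass
class GroundTruth:
    """Per-record truth and per-sample planted repertoires (never emitted
    into pipeline inputs)."""

    records: list[dict]
    planted_repertoires: dict[str, set[str]]

    def artifact_fraction_flagged(self) -> float:
        flagged = [r for r in self.records if r["deamidation_flagged"]]
        if not flagged:
            return float("nan")
        return float(np.mean([r["deamidation_state"] == "artifact" for r in flagged]))


@dataclass
class SimulatedCohort:
    identifications: pd.DataFrame
    peaks: pd.DataFrame
    metadata: pd.DataFrame
    ground_truth: GroundTruth
    config: SynthConfig


def _substring_pool(
    rng: np.random.Generator,
    proteins: list[ProteinRecord],
    n: int,
    length_range: tuple[int, int],
) -> list[tuple[str, str, int]]:
    """Unspecific-digest sampling: (sequence, accession, 1-based offset).

    Sampling is uniform over positions of Q/P-rich proteins, which already
    biases peptides toward the Q/P-rich composition of real gluten digests.
    Distinct sequences only.
    """
    lo, hi = length_range
    capacity = sum(
        max(len(r.sequence) - L + 1, 0) for r in proteins for L in range(lo, hi + 1)
    )
    if n > capacity:
        raise ValueError(f"requested pool of {n} exceeds available distinct substrings")
    pool: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    attempts = 0
    while len(pool) < n and attempts < n * 60:
        attempts += 1
        rec = proteins[int(rng.integers(len(proteins)))]
        L = int(rng.integers(lo, hi + 1))
        if L >= len(rec.sequence):
            continue
        start = int(rng.integers(0, len(rec.sequence) - L + 1))
        seq = rec.sequence[start:start + L]
        key = collapse_il(seq)
        if key in seen:
            continue
        seen.add(key)
        pool.append((seq, rec.accession, start + 1))
    if len(pool) < n:
        raise ValueError(f"requested pool of {n} exceeds available distinct substrings")
    return pool


def _false_sequence(rng: np.random.Generator, length_range: tuple[int, int],
                    forbidden: list[str]) -> str:
    while True:
        L = int(rng.integers(*length_range))
        seq = "".join(rng.choice(_PLAIN_ALPHABET, size=L))
        key = collapse_il(seq)
        if not any(key in collapse_il(f) for f in forbidden):
            return seq


def _lognormal_intensities(rng: np.random.Generator, base: np.ndarray, sigma: float = 0.2
                           ) -> np.ndarray:
    return base * rng.lognormal(0.0, sigma, size=len(base)) * 1e6


def simulate_cohort(
    cfg: SynthConfig, proteomes: dict[str, list[ProteinRecord]] | None = None
) -> SimulatedCohort:
    """Simulate a full identification table + peak lists + metadata + truth."""
    rng = np.random.default_rng(cfg.seed)
    if proteomes is None:
        proteomes = make_toy_proteomes(cfg.proteome_seed)
    wheat = proteomes["wheat"]

    # group-level candidate pools drawn from one master pool so groups share
    # peptides (the shared/triple regions of the set analytics)
    group_means = {
        g: cfg.mean_peptides_control * (cfg.diversity_ratio if g == cfg.elevated_group else 1.0)
        for g, _ in cfg.group_sizes
    }
    pool_sizes = {g: int(np.ceil(cfg.pool_factor * m)) for g, m in group_means.items()}
    master_n = int(1.5 * max(pool_sizes.values())) + 50
    master = _substring_pool(rng, wheat, master_n, cfg.length_range)
    group_pools = {
        g: [master[i] for i in rng.choice(master_n, size=pool_sizes[g], replace=False)]
        for g, _ in cfg.group_sizes
    }

    all_protein_seqs = [r.sequence for recs in proteomes.values() for r in recs]

    id_rows: list[dict] = []
    peak_rows: list[dict] = []
    truth_records: list[dict] = []
    planted: dict[str, set[str]] = {}
    counter = 0

    for group, size in cfg.group_sizes:
        mu = group_means[group]
        k = cfg.nb_dispersion
        for s in range(size):
            sample = f"{group}{s + 1:02d}"
            n_pep = int(rng.negative_binomial(k, k / (k + mu)))
            n_pep = min(max(n_pep, 0), len(group_pools[group]))
            idx = rng.choice(len(group_pools[group]), size=n_pep, replace=False)
            chosen = [group_pools[group][i] for i in idx]
            planted[sample] = set()

            for seq, acc, off in chosen:
                is_false = rng.random() < cfg.false_id_rate
                if is_false:
                    seq_emitted = _false_sequence(rng, cfg.length_range, all_protein_seqs)
                    acc_emitted, off_emitted = "", 0
                else:
                    seq_emitted, acc_emitted, off_emitted = seq, acc, off
                    planted[sample].add(repertoire_key(Peptide(seq)))

                reps = [r for r in range(1, cfg.replicates + 1)
                        if rng.random() < cfg.replicate_detect_prob]
                if not reps:
                    reps = [int(rng.integers(1, cfg.replicates + 1))]

                for rep in reps:
                    counter += 1
                    spectrum_id = f"scan{counter:06d}"
                    row, truth, peaks = _emit_record(
                        rng, cfg, spectrum_id, sample, rep, seq_emitted,
                        is_false, acc_emitted, off_emitted,
                    )
                    id_rows.append(row)
                    truth_records.append(truth)
                    peak_rows.extend(peaks)

    identifications = pd.DataFrame(id_rows)
    peaks = pd.DataFrame(peak_rows, columns=["spectrum_id", "level", "mz", "intensity"])
    metadata = pd.DataFrame(
        [{"sample": f"{g}{i + 1:02d}", "group": g}
         for g, size in cfg.group_sizes for i in range(size)]
    )
    return SimulatedCohort(
        identifications, peaks, metadata, GroundTruth(truth_records, planted), cfg
    )


def _emit_record(
    rng: np.random.Generator,
    cfg: SynthConfig,
    spectrum_id: str,
    sample: str,
    rep: int,
    seq: str,
    is_false: bool,
    acc: str,
    off: int,
) -> tuple[dict, dict, list[dict]]:
    # fixed carbamidomethylation: every Cys is derivatized during workup
    peptide = parse_modified_sequence(seq)
    native_mass = monoisotopic_mass(peptide)
    charge = 2 if native_mass < 2400 else 3
    flagged = (not is_false) and "Q" in seq and rng.random() < cfg.deamidation_rate

    state = "unflagged"
    j = 0
    site = 0
    reported = peptide
    peaks: list[dict] = []

    if flagged:
        q_sites = [i + 1 for i, aa in enumerate(seq) if aa in "NQ"]
        site = int(rng.choice(q_sites))
        reported = Peptide(seq, tuple(sorted(peptide.mods + ((site, "deamidation"),))))
        deam_mass = monoisotopic_mass(reported)
        if rng.random() < cfg.artifact_fraction:
            state = "artifact"
            j = 1 + int(rng.choice(len(cfg.isotope_mispick_probs),
                                   p=np.array(cfg.isotope_mispick_probs)))
            true_neutral = native_mass + j * C13_DELTA
            if cfg.include_spectra:
                env = isotope_envelope(elemental_composition(peptide), max_peaks=6)
                mzs = np.array([m for m, _ in env.mz_peaks(charge)])
                ab = np.array([a for _, a in env.peaks])
                if rng.random() < cfg.suppress_monoisotopic_prob:
                    mzs, ab = mzs[1:], ab[1:]
                inten = _lognormal_intensities(rng, ab)
                for m, i in zip(mzs, inten):
                    peaks.append({"spectrum_id": spectrum_id, "level": "MS1",
                                  "mz": float(m), "intensity": float(i)})
        else:
            state = "genuine"
            true_neutral = deam_mass
            if cfg.include_spectra:
                env = isotope_envelope(elemental_composition(reported), max_peaks=6)
                inten = _lognormal_intensities(rng, np.array([a for _, a in env.peaks]))
                for (m, _), i in zip(env.mz_peaks(charge), inten):
                    peaks.append({"spectrum_id": spectrum_id, "level": "MS1",
                                  "mz": float(m), "intensity": float(i)})
                for m in _localizing_ms2_ions(reported, site):
                    peaks.append({"spectrum_id": spectrum_id, "level": "MS2",
                                  "mz": float(m), "intensity": 1e5})
    else:
        true_neutral = native_mass

    noise = rng.normal(0.0, cfg.mz_noise_ppm * 1e-6) * true_neutral
    obs_mz = (true_neutral + noise + charge * PROTON_MASS) / charge

    row = {
        "sample": sample,
        "replicate": rep,
        "spectrum_id": spectrum_id,
        "sequence": format_modified_sequence(reported),
        "mz": obs_mz,
        "z": charge,
        "score": float(np.round(rng.uniform(20, 90), 2)),
    }
    truth = {
        "spectrum_id": spectrum_id,
        "sample": sample,
        "replicate": rep,
        "true_sequence": seq,
        "true_species": "false_id" if is_false else "wheat",
        "parent_accession": acc,
        "parent_offset": off,
        "deamidation_flagged": flagged,
        "deamidation_state": state,
        "true_site": site,
        "isotope_index": j,
        "true_neutral_mass": true_neutral,
    }
    if cfg.include_spectra:
        peaks.sort(key=lambda p: (p["level"], p["mz"]))
    return row, truth, peaks


def _localizing_ms2_ions(p: Peptide, site: int) -> list[float]:
    """Minimal shifted-ion set uniquely localizing a deamidation site.

    One prefix ion ending at the site plus one suffix ion starting at it:
    any other candidate site is covered by at most one of the two.
    """
    n = len(p)
    ions: list[float] = []
    if site < n:
        native, deam = site_determining_ions(p, site, "b")
        ions.append(deam[0])  # b ion of length `site`
    else:
        native, deam = site_determining_ions(p, site, "y")
        ions.append(deam[0])  # y1
    if site > 1:
        native, deam = site_determining_ions(p, site, "y")
        ions.append(deam[0])  # y ion of length n-site+1
    else:
        native, deam = site_determining_ions(p, site, "c")
        ions.append(deam[0])  # c1
    return sorted(set(ions))


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the pipeline-dialect files: identifications CSV, peak-list TSV,
    metadata TSV, and the ground truth JSON (for evaluation only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "identifications": outdir / "identifications.csv",
        "peaks": outdir / "peaks.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    cohort.identifications.to_csv(paths["identifications"], index=False, float_format="%.6f")
    cohort.peaks.to_csv(paths["peaks"], sep="\t", index=False, float_format="%.6f")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    gt = {
        "records": cohort.ground_truth.records,
        "planted_repertoires": {
            k: sorted(v) for k, v in cohort.ground_truth.planted_repertoires.items()
        },
    }
    paths["ground_truth"].write_text(json.dumps(gt, indent=1))
    return paths
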