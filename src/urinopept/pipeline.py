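"""End-to-end orchestration: parse → audit → assign → annotate → analyze.

The pipeline consumes an identification CSV, an optional peak-list TSV and
a sample metadata TSV, plus FASTA databases, and emits a report bundle of
tab-separated tables and JSON documents with a reproducible manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .assign import IdentificationRecord, assign_species, sample_repertoire
from .audit import AuditConfig
from .cohort import (
    SampleSet,
    count_table,
    coverage_frame,
    coverage_matrix,
    frequency_ranking,
    group_compare,
    set_intersections,
)
from .immuno import epitope_count_table, load_epitope_catalogue, peptides_with_epitope
from .io import audit_records, read_identifications, read_peak_lists
from .proteome import ProteomeDB, build_database, read_fasta

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

logger = logging.getLogger("urinopept")


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable run configuration (single JSON document)."""

    identifications: str
    metadata: str
    human_fasta: tuple[str, ...] = ()
    grain_fastas: tuple[tuple[str, str], ...] = ()  # (species label, path)
    peak_lists: str | None = None
    output_dir: str = "urinopept_out"
    audit: AuditConfig = AuditConfig()
    epitope_catalogue: str | None = None
    coverage_accessions: tuple[str, ...] = ()
    species_of_interest: str = "wheat"
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["audit"] = dataclasses.asdict(self.audit)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "audit" in d:
            audit_known = {f.name for f in dataclasses.fields(AuditConfig)}
            audit_unknown = set(d["audit"]) - audit_known
            if audit_unknown:
                raise ValueError(f"unknown audit key(s): {sorted(audit_unknown)}")
            d["audit"] = AuditConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in d["audit"].items()
            })
        for k in ("human_fasta", "coverage_accessions"):
            if k in d:
                d[k] = tuple(d[k])
        if "grain_fastas" in d:
            d["grain_fastas"] = tuple((a, b) for a, b in d["grain_fastas"])
        return cls(**d)


@dataclass
class ReportBundle:
    """Paths of every emitted artifact plus the run manifest."""

    output_dir: Path
    audit_table: Path
    assignment_table: Path
    repertoires: Path
    epitope_counts: Path
    coverage_tables: dict[str, Path]
    statistics: Path
    manifest: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cfg: PipelineConfig,
    human_db: ProteomeDB | None = None,
    grain_dbs: Mapping[str, ProteomeDB] | None = None,
) -> ReportBundle:
    """Run all stages in fixed order and write the report bundle.

    Databases may be passed in-memory (they win over the FASTA paths in the
    config); every exclusion is logged with a machine-parseable reason code.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: parse
    try:
        records = read_identifications(cfg.identifications, strict=True)
    except ValueError as exc:
        raise RuntimeError(f"stage=parse failed: {exc}") from exc
    metadata = pd.read_csv(cfg.metadata, sep="\t")
    groups = dict(zip(metadata["sample"].astype(str), metadata["group"].astype(str)))
    unknown = {r.sample_id for r in records} - set(groups)
    if unknown:
        raise RuntimeError(f"stage=parse failed: samples missing from metadata: {sorted(unknown)}")

    if human_db is None and cfg.human_fasta:
        human_db = build_database(curated_files=cfg.human_fasta, keywords=())
    if grain_dbs is None:
        grain_dbs = {}
        for label, path in cfg.grain_fastas:
            grain_dbs.setdefault(label, build_database(curated_files=[path]))

    # -- stage: audit
    spectra = read_peak_lists(cfg.peak_lists) if cfg.peak_lists else {}
    audit_df = audit_records(records, spectra, cfg.audit)
    verdicts = dict(zip(audit_df["spectrum_id"], audit_df["verdict"]))

    # -- stage: assign
    catalogue = load_epitope_catalogue(cfg.epitope_catalogue)
    kept = [r for r in records if verdicts.get(r.spectrum_id) != "AMBIGUOUS_EXCLUDED"]
    assign_rows = []
    assignment_cache: dict[str, tuple[str, str]] = {}
    for rec in kept:
        native = rec.peptide.without("deamidation")
        if native.sequence not in assignment_cache:
            a = assign_species(native.sequence, human_db, grain_dbs)
            assignment_cache[native.sequence] = (
                a.species, ";".join(f"{d}:{acc}:{off}" for d, acc, off in a.matches)
            )
        species, matches = assignment_cache[native.sequence]
        assign_rows.append({
            "spectrum_id": rec.spectrum_id,
            "sample": rec.sample_id,
            "sequence": native.sequence,
            "species": species,
            "matches": matches,
        })
    assign_df = pd.DataFrame(assign_rows)

    # -- stage: annotate + analyze (repertoires of the species of interest)
    species_records = [
        r for r in kept
        if assignment_cache[r.peptide.without("deamidation").sequence][0] == cfg.species_of_interest
    ]
    repertoires = sample_repertoire(species_records, verdicts)
    sample_set = SampleSet(
        groups, {s: frozenset(repertoires.get(s, set())) for s in groups}
    )
    counts_df = count_table(sample_set)
    group_reps = {g: sample_set.union_repertoire(g) for g in sample_set.group_labels()}
    epitope_df = epitope_count_table(
        {g: rep for g, rep in group_reps.items() if rep} or
        {g: {""} for g in group_reps},  # degenerate: all groups empty
        catalogue,
    )
    regions = set_intersections(group_reps) if len(group_reps) >= 2 else {}
    ranking = frequency_ranking(repertoires)

    stats_obj: dict = {"per_sample_counts": counts_df.to_dict(orient="records")}
    label_counts = dict(zip(counts_df["sample"], counts_df["n_peptides"]))
    group_of = dict(zip(counts_df["sample"], counts_df["group"]))
    if len(set(group_of.values())) >= 2 and all(
        list(group_of.values()).count(g) >= 2 for g in set(group_of.values())
    ):
        cmp = group_compare(label_counts, group_of)
        stats_obj["kruskal_wallis"] = {"H": cmp.statistic, "p": cmp.pvalue}
        stats_obj["medians"] = cmp.medians
        stats_obj["dunn"] = cmp.pairwise.to_dict(orient="records")
    stats_obj["set_regions"] = {"+".join(sorted(k)): v for k, v in regions.items()}
    stats_obj["epitope_peptides_per_sample"] = {
        s: len(peptides_with_epitope(sample_set.repertoires[s], catalogue))
        for s in sample_set.samples()
    }

    # -- write bundle
    paths = ReportBundle(
        output_dir=out,
        audit_table=out / "audit.tsv",
        assignment_table=out / "assignments.tsv",
        repertoires=out / "repertoires.json",
        epitope_counts=out / "epitope_counts.tsv",
        coverage_tables={},
        statistics=out / "statistics.json",
        manifest=out / "manifest.json",
    )
    audit_df.to_csv(paths.audit_table, sep="\t", index=False, float_format="%.6f")
    assign_df.to_csv(paths.assignment_table, sep="\t", index=False)
    paths.repertoires.write_text(
        json.dumps({s: sorted(v) for s, v in repertoires.items()}, indent=1, sort_keys=True)
    )
    epitope_df.to_csv(paths.epitope_counts, sep="\t")
    (out / "frequency_ranking.tsv").write_text(ranking.to_csv(sep="\t", index=False))

    cov_accessions = list(cfg.coverage_accessions)
    for label, db in (grain_dbs or {}).items():
        if label != cfg.species_of_interest:
            continue
        for acc in cov_accessions:
            if acc in db:
                cov = coverage_matrix(db.get(acc), sample_set, catalogue)
                p = out / f"coverage_{acc}.tsv"
                coverage_frame(cov).to_csv(p, sep="\t", float_format="%.4f")
                paths.coverage_tables[acc] = p
    paths.statistics.write_text(json.dumps(stats_obj, indent=1, sort_keys=True, default=float))

    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
        "n_records": len(records),
        "n_excluded": int((audit_df["verdict"] == "AMBIGUOUS_EXCLUDED").sum()),
    }
    paths.manifest.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths
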