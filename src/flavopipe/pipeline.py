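"""End-to-end orchestration of the 16S and gene-content analyses.

`run_full_16s` chains rarefaction -> low-count OTU filter -> diversity and
ordination -> pairing/prevalence filters -> paired differential test with
BH correction, writing per-stage TSVs and a JSON summary of the counts
surviving each filter. `run_characteristic_genes` chains sample
classification -> coverage-based presence calls -> five-tier gene
categorization -> transporter-keyword enrichment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io as fio
from .chargenes import (
    annotate_keywords,
    call_gene_presence,
    categorize_genes,
    characteristic_gene_set,
    classify_samples,
    functional_enrichment,
)
from .community import (
    alpha_diversity_table,
    bray_curtis,
    compare_shift_magnitude,
    compare_within_between_subject,
    filter_min_total_reads,
    pcoa,
    rarefy_table,
)
from .differential import differential_features, filter_for_differential
from .types import (
    AnalysisConfig,
    Arm,
    GeneRecord,
    OtuTable,
    SampleRecord,
    Visit,
)

log = logging.getLogger("flavopipe")


@dataclass
class RunConfig:
    """Paths and thresholds of a pipeline run; the seed is recorded in
    every output header."""

    otu_table: Optional[str] = None
    metadata: Optional[str] = None
    gene_table: Optional[str] = None
    gene_coverage: Optional[str] = None
    relabund: Optional[str] = None
    outdir: str = "flavopipe_out"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def config_dict(self) -> dict:
        d = asdict(self)
        return d


class StageError(RuntimeError):
    """Raised when a named pipeline stage fails."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(name, exc) from exc

    return wrap


def run_full_16s(
    config: RunConfig,
    table: Optional[OtuTable] = None,
    meta: Optional[Sequence[SampleRecord]] = None,
) -> dict:
    """Run the full 16S analysis; returns the summary dict (also written
    as JSON). Inputs may be passed in memory or read from the config paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.analysis

    if table is None:
        if config.otu_table is None:
            raise StageError("load_inputs", ValueError("no OTU table provided"))
        table = _stage("load_inputs")(fio.read_otu_table, config.otu_table)
    if meta is None:
        if config.metadata is None:
            raise StageError("load_inputs", ValueError("no metadata provided"))
        meta = _stage("load_inputs")(fio.read_metadata, config.metadata)
    if not meta:
        raise StageError("load_inputs", ValueError("metadata is empty"))

    summary: dict = {
        "seed": config.seed,
        "raw_samples": len(table.sample_ids),
        "raw_otus": len(table.otu_ids),
    }

    non_uti_ids = [
        r.sample_id
        for r in meta
        if r.visit is not Visit.UTI_EVENT and r.sample_id in set(table.sample_ids)
    ]
    table = _stage("exclude_uti_samples")(table.subset_samples, non_uti_ids)
    summary["non_uti_samples"] = len(table.sample_ids)

    rarefied = _stage("rarefy")(rarefy_table, table, cfg.rarefaction_depth, config.seed)
    nonzero = rarefied.counts.columns[rarefied.counts.sum(axis=0) > 0]
    rarefied = rarefied.subset_otus(list(nonzero))
    summary["rarefied_samples"] = len(rarefied.sample_ids)
    summary["rarefied_otus"] = len(rarefied.otu_ids)

    filtered = _stage("min_total_filter")(
        filter_min_total_reads, rarefied, cfg.min_total_reads_per_otu
    )
    summary["post_min_total_otus"] = len(filtered.otu_ids)
    fio.write_otu_table(
        filtered, outdir / "rarefied_filtered_otu_table.tsv", config.seed,
        config.config_dict(),
    )

    alpha = _stage("alpha_diversity")(alpha_diversity_table, filtered)
    fio.write_result_table(alpha, outdir / "alpha_diversity.tsv", config.seed)

    dm = _stage("beta_diversity")(bray_curtis, filtered)
    fio.write_distance_matrix(dm, outdir / "bray_curtis.tsv", config.seed)
    ordination = _stage("pcoa")(pcoa, dm)
    fio.write_result_table(
        ordination.coordinates.reset_index(names="sample_id"),
        outdir / "pcoa_coordinates.tsv",
        config.seed,
    )
    summary["pcoa_explained_pct"] = [
        round(100 * float(f), 2) for f in ordination.explained_fraction[:2]
    ]

    try:
        w, b, p_wb = compare_within_between_subject(dm, meta)
        summary["within_between"] = {
            "median_within": w,
            "median_between": b,
            "p": p_wb,
        }
    except ValueError as exc:
        summary["within_between"] = {"skipped": str(exc)}
    try:
        mc, mp, p_shift = compare_shift_magnitude(dm, meta)
        summary["shift_comparison"] = {
            "median_shift_cranberry": mc,
            "median_shift_placebo": mp,
            "p": p_shift,
        }
    except ValueError as exc:
        summary["shift_comparison"] = {"skipped": str(exc)}

    diff_table, subjects = _stage("pairing_prevalence_filter")(
        filter_for_differential, filtered, meta, cfg
    )
    arm_of = {r.subject_id: r.arm for r in meta}
    summary["post_prevalence_otus"] = len(diff_table.otu_ids)
    summary["paired_subjects_cranberry"] = sum(
        1 for s in subjects if arm_of[s] is Arm.CRANBERRY
    )
    summary["paired_subjects_placebo"] = sum(
        1 for s in subjects if arm_of[s] is Arm.PLACEBO
    )

    results = _stage("differential_test")(differential_features, diff_table, meta, cfg)
    fio.write_result_table(
        results, outdir / "differential_otus.tsv", config.seed, config.config_dict()
    )
    significant = results.loc[results.p_adj < cfg.alpha, "feature_id"]
    summary["n_significant"] = int(len(significant))
    summary["significant_features"] = list(significant)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("16S pipeline complete: %s", summary)
    return summary


def run_characteristic_genes(
    config: RunConfig,
    genes: Optional[Sequence[GeneRecord]] = None,
    coverage=None,
    relabund: Optional[Mapping[str, float]] = None,
) -> dict:
    """Run the gene-content analysis; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if genes is None:
        if config.gene_table is None:
            raise StageError("load_inputs", ValueError("no gene table provided"))
        genes = _stage("load_inputs")(fio.read_gene_table, config.gene_table)
    if coverage is None:
        if config.gene_coverage is None:
            raise StageError("load_inputs", ValueError("no coverage table provided"))
        coverage = _stage("load_inputs")(fio.read_gene_coverage, config.gene_coverage)
    if relabund is None:
        if config.relabund is None:
            raise StageError("load_inputs", ValueError("no relative-abundance map provided"))
        import pandas as pd

        df = fio._read_tsv(config.relabund)
        relabund = dict(zip(df["sample_id"].astype(str), df["relabund"].astype(float)))

    classes = _stage("classify_samples")(classify_samples, relabund)
    presence = _stage("gene_presence")(call_gene_presence, coverage)
    report = _stage("categorize_genes")(categorize_genes, presence, classes, genes)
    fio.write_result_table(
        report, outdir / "characteristic_genes.tsv", config.seed, config.config_dict()
    )

    summary: dict = {
        "seed": config.seed,
        "n_genes": len(report),
        "n_pos_samples": sum(1 for c in classes if c.label.value == "otu41_pos"),
        "n_neg_samples": sum(1 for c in classes if c.label.value == "otu41_neg"),
    }
    unique_available = bool(report["unique_flag_available"].all())
    summary["unique_flag_available"] = unique_available
    counts: dict[str, object] = {}
    for cat in range(6):
        if not unique_available and cat in (3, 5):
            counts[str(cat)] = "unavailable"
        else:
            counts[str(cat)] = int((report["category"] == cat).sum())
    summary["category_counts"] = counts

    char_set = characteristic_gene_set(report, min_category=5 if unique_available else 4)
    summary["n_characteristic"] = len(char_set)
    if char_set:
        flags = annotate_keywords(genes)
        enrichment = _stage("functional_enrichment")(
            functional_enrichment, flags, char_set, genes
        )
        summary["transporter_enrichment"] = {
            "table": [[enrichment.a, enrichment.b], [enrichment.c, enrichment.d]],
            "odds_ratio": enrichment.odds_ratio,
            "p": enrichment.p,
        }
        (outdir / "enrichment.json").write_text(
            json.dumps(summary["transporter_enrichment"], indent=2)
        )
    (outdir / "char_genes_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    log.info("characteristic-gene pipeline complete: %s", summary)
    return summary
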