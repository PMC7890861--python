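"""Paired differential-abundance testing of OTUs and functional features.

The core statistic: for each feature, each paired subject contributes
log2((reads_wk24 + c) / (reads_wk0 + c)); the two study arms' fold-change
distributions are compared with a two-sided Wilcoxon rank-sum test and
p-values are Benjamini-Hochberg corrected across features. A subject with
no reads at either timepoint contributes a fold-change of exactly 0.

Also here: the prevalence/pairing filters applied beforehand, an orthogonal
validation on per-subject differences of relative frequencies, the variant
for functional (pathway / gene-family) tables with per-arm prevalence
filtering and small pseudocounts, and exact-sequence read counting for
verifying a 16S result in shotgun data.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .stats import bh_adjust, wilcoxon_rank_sum
from .types import AnalysisConfig, Arm, OtuTable, SampleRecord, Visit


def paired_subjects(
    meta: Sequence[SampleRecord], sample_ids: Sequence[str]
) -> dict[str, dict[Visit, str]]:
    """Subjects with both a week-0 and a week-24 sample among ``sample_ids``
    (UTI-visit samples ignored), mapped to their per-visit sample ids."""
    present = set(sample_ids)
    by_subject: dict[str, dict[Visit, str]] = {}
    for r in meta:
        if r.visit is Visit.UTI_EVENT or r.sample_id not in present:
            continue
        by_subject.setdefault(r.subject_id, {})[r.visit] = r.sample_id
    return {
        s: v for s, v in by_subject.items() if Visit.WEEK0 in v and Visit.WEEK24 in v
    }


def arm_of_subjects(meta: Sequence[SampleRecord]) -> dict[str, Arm]:
    return {r.subject_id: r.arm for r in meta}


def filter_for_differential(
    table: OtuTable, meta: Sequence[SampleRecord], cfg: AnalysisConfig
) -> tuple[OtuTable, list[str]]:
    """Restrict a (rarefied) table to paired subjects and prevalent OTUs.

    Keeps only samples from subjects with both timepoints, then OTUs present
    (>= 1 read) in at least ``cfg.prevalence_fraction`` of those samples,
    pooled across arms and timepoints.
    """
    pairs = paired_subjects(meta, table.sample_ids)
    if not pairs:
        raise ValueError("no subject has samples at both week 0 and week 24")
    kept_samples = [sid for visits in pairs.values() for sid in visits.values()]
    sub = table.subset_samples(kept_samples)
    prevalence = (sub.counts > 0).mean(axis=0)
    keep_otus = prevalence.index[prevalence >= cfg.prevalence_fraction]
    if len(keep_otus) == 0:
        raise ValueError("no OTU passes the prevalence filter")
    return sub.subset_otus(list(keep_otus)), sorted(pairs)


def log2_fold_change(
    reads_wk0: float, reads_wk24: float, pseudocount: float = 1.0
) -> float:
    """log2((reads_wk24 + c) / (reads_wk0 + c)); 0 when both counts are 0."""
    if reads_wk0 < 0 or reads_wk24 < 0:
        raise ValueError("read counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((reads_wk24 + pseudocount) / (reads_wk0 + pseudocount)))


def _fold_change_matrix(
    values: pd.DataFrame,
    pairs: Mapping[str, Mapping[Visit, str]],
    pseudocount: float,
) -> pd.DataFrame:
    """Subjects x features matrix of paired log2 fold-changes.

    ``values`` is samples x features; each subject's row is
    log2((wk24 + c) / (wk0 + c)) computed feature-wise.
    """
    subjects = sorted(pairs)
    wk0 = values.loc[[pairs[s][Visit.WEEK0] for s in subjects]].to_numpy(dtype=float)
    wk24 = values.loc[[pairs[s][Visit.WEEK24] for s in subjects]].to_numpy(dtype=float)
    fc = np.log2((wk24 + pseudocount) / (wk0 + pseudocount))
    return pd.DataFrame(fc, index=subjects, columns=values.columns)


def _arm_compare(
    fc: pd.DataFrame, arm_of: Mapping[str, Arm]
) -> pd.DataFrame:
    """Per-feature arm medians, their difference, rank-sum p and BH p_adj."""
    cran = [s for s in fc.index if arm_of[s] is Arm.CRANBERRY]
    plac = [s for s in fc.index if arm_of[s] is Arm.PLACEBO]
    if not cran or not plac:
        raise ValueError("both study arms need at least one paired subject")
    rows = []
    for feature in fc.columns:
        x = fc.loc[cran, feature].to_numpy()
        y = fc.loc[plac, feature].to_numpy()
        rows.append(
            (
                feature,
                len(cran),
                len(plac),
                float(np.median(x)),
                float(np.median(y)),
                float(np.median(x) - np.median(y)),
                wilcoxon_rank_sum(x, y),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "n_subjects_cranberry",
            "n_subjects_placebo",
            "median_fc_cranberry",
            "median_fc_placebo",
            "delta",
            "p",
        ],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p_adj", "p"], kind="mergesort").reset_index(drop=True)


def differential_features(
    table: OtuTable, meta: Sequence[SampleRecord], cfg: AnalysisConfig
) -> pd.DataFrame:
    """Per-OTU paired fold-change comparison between arms.

    Expects the output of :func:`filter_for_differential`. Returns one row
    per feature sorted by (p_adj, p) with per-arm subject counts, per-arm
    median log2 fold-changes, their difference, and raw/BH-adjusted p.
    """
    pairs = paired_subjects(meta, table.sample_ids)
    if not pairs:
        raise ValueError("no paired subjects in table")
    fc = _fold_change_matrix(table.counts, pairs, cfg.otu_pseudocount)
    return _arm_compare(fc, arm_of_subjects(meta))


def pairwise_differences_validation(
    relabund: pd.DataFrame, meta: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Orthogonal check on relative frequencies: per subject compute
    relfreq_wk24 - relfreq_wk0 per feature, compare arms by rank-sum, BH
    across features."""
    if not np.allclose(relabund.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of the relative-abundance table must sum to 1")
    pairs = paired_subjects(meta, list(relabund.index))
    if not pairs:
        raise ValueError("no paired subjects in table")
    subjects = sorted(pairs)
    wk0 = relabund.loc[[pairs[s][Visit.WEEK0] for s in subjects]].to_numpy()
    wk24 = relabund.loc[[pairs[s][Visit.WEEK24] for s in subjects]].to_numpy()
    diffs = pd.DataFrame(wk24 - wk0, index=subjects, columns=relabund.columns)
    arm_of = arm_of_subjects(meta)
    cran = [s for s in subjects if arm_of[s] is Arm.CRANBERRY]
    plac = [s for s in subjects if arm_of[s] is Arm.PLACEBO]
    rows = []
    for feature in diffs.columns:
        x = diffs.loc[cran, feature].to_numpy()
        y = diffs.loc[plac, feature].to_numpy()
        if np.all(x == 0) and np.all(y == 0):
            p = 1.0
        else:
            p = wilcoxon_rank_sum(x, y)
        rows.append((feature, float(np.median(x)), float(np.median(y)), p))
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "median_diff_cranberry", "median_diff_placebo", "p"],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p_adj", "p"], kind="mergesort").reset_index(drop=True)


def differential_pathways(
    feature_table: pd.DataFrame,
    meta: Sequence[SampleRecord],
    cfg: AnalysisConfig,
    pseudocount: float,
) -> pd.DataFrame:
    """Differential test for functional feature tables (features x samples).

    A feature is retained only if present (> 0) in at least
    ``cfg.feature_prevalence_fraction`` of the paired subjects of *each*
    arm (a subject counts as positive if either of its samples is nonzero).
    Fold-changes use the supplied pseudocount (0.001 for pathways, 0.0001
    for gene families by convention).
    """
    if (feature_table.to_numpy() < 0).any():
        raise ValueError("feature abundances must be non-negative")
    values = feature_table.T  # samples x features
    pairs = paired_subjects(meta, list(values.index))
    if not pairs:
        raise ValueError("no paired subjects in feature table")
    arm_of = arm_of_subjects(meta)
    subjects = sorted(pairs)
    arms = {arm: [s for s in subjects if arm_of[s] is arm] for arm in Arm}
    if not arms[Arm.CRANBERRY] or not arms[Arm.PLACEBO]:
        raise ValueError("both study arms need paired subjects")
    present = {}
    for s in subjects:
        rows = values.loc[[pairs[s][Visit.WEEK0], pairs[s][Visit.WEEK24]]]
        present[s] = (rows > 0).any(axis=0)
    presence = pd.DataFrame(present).T  # subjects x features
    keep = values.columns[
        (presence.loc[arms[Arm.CRANBERRY]].mean(axis=0) >= cfg.feature_prevalence_fraction)
        & (presence.loc[arms[Arm.PLACEBO]].mean(axis=0) >= cfg.feature_prevalence_fraction)
    ]
    if len(keep) == 0:
        raise ValueError("no feature passes the per-arm prevalence filter")
    fc = _fold_change_matrix(values[list(keep)], pairs, pseudocount)
    return _arm_compare(fc, arm_of)


def exact_sequence_abundance(
    sample_reads: Mapping[str, Sequence[Union[str, tuple[str, str]]]],
    query: str,
    min_query_length: int = 50,
) -> dict[str, float]:
    """Per-sample relative abundance of reads exactly matching a query.

    A read counts if its full sequence occurs verbatim as a substring of
    the query or of its reverse complement (no mismatches). The count is
    divided by the sample's total read count.
    """
    if not query:
        raise ValueError("query must be non-empty")
    query = query.upper()
    if len(query) < min_query_length:
        raise ValueError(f"query shorter than {min_query_length} nt")
    rc = str(Seq(query).reverse_complement())
    out = {}
    for sample_id, reads in sample_reads.items():
        seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
        if not seqs:
            raise ValueError(f"sample {sample_id!r} has no reads")
        hits = sum(1 for s in seqs if s.upper() in query or s.upper() in rc)
        out[sample_id] = hits / len(seqs)
    return out
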