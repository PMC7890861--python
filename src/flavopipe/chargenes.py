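"""Characteristic-gene analysis: which reference genes travel with the
focal OTU across metagenomic samples.

Samples are split into OTU-positive (>= 0.9% 16S relative abundance) and
OTU-negative (< 0.01%) classes; a gene is "present" in a sample when at
least 75% of its length has read coverage. Genes are then placed in five
tiers of increasing stringency, from Fisher-exact enrichment in positive
samples up to presence in every positive sample, absence from every
negative sample, and exclusivity to the reference genome's orthogroups.
Transporter-like genes are flagged by keyword search over annotations and
tested for enrichment among the characteristic set.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact
from .types import (
    EnrichmentTable,
    GeneCoverage,
    GeneRecord,
    SampleClass,
    SampleClassLabel,
)

PRESENCE_THRESHOLD = 0.75
POS_RELABUND_THRESHOLD = 0.009
NEG_RELABUND_THRESHOLD = 0.0001
TRANSPORTER_KEYWORDS = ("transport", "symport", "permease", "efflux", "pump", "antiport")


def call_gene_presence(
    coverage: Sequence[GeneCoverage], threshold: float = PRESENCE_THRESHOLD
) -> pd.DataFrame:
    """Gene x sample boolean presence matrix: present iff the covered
    fraction is at least ``threshold`` (inclusive)."""
    seen = set()
    for c in coverage:
        key = (c.gene_id, c.sample_id)
        if key in seen:
            raise ValueError(f"duplicate coverage entry for {key}")
        seen.add(key)
    df = pd.DataFrame(
        [(c.gene_id, c.sample_id, c.covered_fraction) for c in coverage],
        columns=["gene_id", "sample_id", "covered_fraction"],
    )
    wide = df.pivot(index="gene_id", columns="sample_id", values="covered_fraction")
    if wide.isna().any().any():
        raise ValueError("coverage table is not complete over genes x samples")
    return wide >= threshold


def classify_samples(
    relabund: Mapping[str, float],
    pos_threshold: float = POS_RELABUND_THRESHOLD,
    neg_threshold: float = NEG_RELABUND_THRESHOLD,
) -> list[SampleClass]:
    """Split samples by focal-OTU relative abundance: positive at
    >= pos_threshold, negative strictly below neg_threshold, everything in
    between (including exactly neg_threshold) unclassified and excluded
    downstream."""
    classes = []
    for sample_id, value in relabund.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"relative abundance out of [0,1] for {sample_id!r}")
        if value >= pos_threshold:
            label = SampleClassLabel.OTU41_POS
        elif value < neg_threshold:
            label = SampleClassLabel.OTU41_NEG
        else:
            label = SampleClassLabel.UNCLASSIFIED
        classes.append(SampleClass(sample_id, label, value))
    return classes


def categorize_genes(
    presence: pd.DataFrame,
    classes: Sequence[SampleClass],
    genes: Sequence[GeneRecord],
    pos_full: Optional[int] = None,
    neg_zero_max: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each gene its characteristic-gene category.

    Categories (a gene gets the highest whose rule it meets):
      1  enriched in positive samples (Fisher exact, BH-adjusted p < alpha,
         positive coverage fraction exceeding negative)
      2  highly enriched: covered in >= (n_pos - 1) positive and <= 1
         negative samples
      3  category 2 and unique to the reference genome's orthogroups
      4  OTU-specific: covered in all ``pos_full`` (default: all) positive
         samples and <= ``neg_zero_max`` (default 0) negative samples
      5  category 4 and unique to the reference
      0  none of the above

    When the gene records carry no orthogroup-uniqueness information the
    uniqueness-dependent categories (3, 5) are reported as NA rather than
    silently zero.
    """
    pos = [c.sample_id for c in classes if c.label is SampleClassLabel.OTU41_POS]
    neg = [c.sample_id for c in classes if c.label is SampleClassLabel.OTU41_NEG]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative sample")
    missing = (set(pos) | set(neg)) - set(presence.columns)
    if missing:
        raise ValueError(f"classified samples missing from presence matrix: {sorted(missing)}")
    n_pos, n_neg = len(pos), len(neg)
    pos_full = n_pos if pos_full is None else pos_full
    high_pos_min, high_neg_max = n_pos - 1, 1

    unique_of = {g.gene_id: g.unique_to_reference for g in genes}
    unique_known = all(v is not None for v in unique_of.values())

    rows = []
    for gene_id in presence.index:
        if gene_id not in unique_of:
            raise ValueError(f"gene {gene_id!r} absent from gene records")
        n_pos_cov = int(presence.loc[gene_id, pos].sum())
        n_neg_cov = int(presence.loc[gene_id, neg].sum())
        _, p = fisher_exact(n_pos_cov, n_pos - n_pos_cov, n_neg_cov, n_neg - n_neg_cov)
        rows.append((gene_id, n_pos_cov, n_neg_cov, p))
    report = pd.DataFrame(
        rows, columns=["gene_id", "n_pos_covered", "n_neg_covered", "enrichment_p"]
    )
    report["enrichment_p_adj"] = bh_adjust(report["enrichment_p"].to_numpy())

    categories = []
    for r in report.itertuples():
        unique = unique_of[r.gene_id]
        enriched_direction = (r.n_pos_covered / n_pos) > (r.n_neg_covered / n_neg)
        cat = 0
        if r.enrichment_p_adj < alpha and enriched_direction:
            cat = 1
        if r.n_pos_covered >= high_pos_min and r.n_neg_covered <= high_neg_max:
            cat = 2
            if unique_known and unique:
                cat = 3
        if r.n_pos_covered >= pos_full and r.n_neg_covered <= neg_zero_max:
            cat = 4
            if unique_known and unique:
                cat = 5
        categories.append(cat)
    report["category"] = categories
    report["unique_flag_available"] = unique_known
    if not unique_known:
        report["category"] = report["category"].astype("object")
        report.loc[report["category"].isin([3, 5]), "category"] = pd.NA
    return report


def characteristic_gene_set(report: pd.DataFrame, min_category: int = 4) -> set[str]:
    """Gene ids at or above a category tier (default: the OTU-specific
    tiers 4/5 that define the characteristic set)."""
    mask = report["category"].apply(
        lambda c: isinstance(c, (int, np.integer)) and c >= min_category
    )
    return set(report.loc[mask, "gene_id"])


def annotate_keywords(
    genes: Sequence[GeneRecord],
    keywords: Sequence[str] = TRANSPORTER_KEYWORDS,
) -> dict[str, bool]:
    """Flag genes whose product, COG, GO or Pfam text contains any keyword
    as a case-insensitive substring (so 'antiport' matches 'antiporter')."""
    lowered = [k.lower() for k in keywords]
    flags = {}
    for g in genes:
        text = " ".join((g.product, g.cog, g.go, g.pfam)).lower()
        flags[g.gene_id] = any(k in text for k in lowered)
    return flags


def functional_enrichment(
    flags: Mapping[str, bool],
    characteristic_set: Iterable[str],
    all_genes: Sequence[GeneRecord],
    inclusive_background: bool = False,
) -> EnrichmentTable:
    """Fisher-exact enrichment of flagged genes in the characteristic set.

    The default 2x2 table compares the characteristic set against the
    remaining genes (background excludes the set); the inclusive flag
    compares against all genes instead.
    """
    characteristic = set(characteristic_set)
    if not characteristic:
        raise ValueError("characteristic gene set is empty")
    all_ids = [g.gene_id for g in all_genes]
    if not characteristic <= set(all_ids):
        raise ValueError("characteristic set contains unknown gene ids")
    a = sum(1 for g in characteristic if flags[g])
    b = len(characteristic) - a
    background = all_ids if inclusive_background else [
        g for g in all_ids if g not in characteristic
    ]
    c = sum(1 for g in background if flags[g])
    d = len(background) - c
    odds, p = fisher_exact(a, b, c, d)
    return EnrichmentTable(a=a, b=b, c=c, d=d, odds_ratio=odds, p=p)
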