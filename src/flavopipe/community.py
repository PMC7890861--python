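"""Community-level profiling of 16S OTU tables.

Covers depth normalization by rarefaction, alpha diversity (bias-corrected
Chao1 richness and base-2 Shannon entropy), Bray-Curtis beta diversity,
principal coordinates analysis, and the two cohort-structure comparisons
used on the dissimilarity matrix: same-subject vs different-subject
distances, and the per-subject week0->week24 shift compared between study
arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon

from .stats import wilcoxon_rank_sum
from .types import OtuTable, SampleRecord, Visit


def rarefy_table(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total read count is below ``depth`` are dropped rather
    than padded. Deterministic for a fixed seed.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_rows = {}
    for sample_id, row in table.counts.iterrows():
        counts = row.to_numpy()
        total = int(counts.sum())
        if total < depth:
            continue
        # multivariate hypergeometric == uniform subsample w/o replacement
        kept_rows[sample_id] = rng.multivariate_hypergeometric(counts, depth)
    if not kept_rows:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    df = pd.DataFrame.from_dict(kept_rows, orient="index", columns=table.otu_ids)
    df.index.name = table.counts.index.name
    return OtuTable(df, table.taxonomy)


def filter_min_total_reads(table: OtuTable, min_total: int = 10) -> OtuTable:
    """Drop OTUs with fewer than ``min_total`` reads summed over samples,
    removing rare/ultra-low-abundance OTUs after rarefaction."""
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= min_total]
    if len(keep) == 0:
        raise ValueError("no OTU passes the minimum total-read filter")
    return table.subset_otus(list(keep))


def rarefaction_depth_scan(
    table: OtuTable, depths: Sequence[int], seed: int
) -> pd.DataFrame:
    """Rarefy at each candidate depth and tabulate mean Chao1 richness and
    the number of samples retained, to pick a working depth."""
    if len(depths) == 0 or min(depths) < 1:
        raise ValueError("depths must be non-empty positive integers")
    rows = []
    for depth in depths:
        totals = table.counts.sum(axis=1)
        retained = int((totals >= depth).sum())
        if retained == 0:
            rows.append((depth, np.nan, 0))
            continue
        rarefied = rarefy_table(table, depth, seed)
        chao1_values = [chao1(row.to_numpy()) for _, row in rarefied.counts.iterrows()]
        rows.append((depth, float(np.mean(chao1_values)), retained))
    return pd.DataFrame(rows, columns=["depth", "mean_chao1", "samples_retained"])


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("need at least one positive count")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def chao1(counts: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)) in the bias-corrected
    form (F1 singletons, F2 doubletons); classic form via the flag."""
    counts = _check_counts(counts)
    return float(_skbio_chao1(counts.astype(int), bias_corrected=bias_corrected))


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity in bits: -sum p_i log2 p_i over nonzero proportions."""
    counts = _check_counts(np.asarray(counts, dtype=float))
    return float(_skbio_shannon(counts, base=2))


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon values."""
    rows = [
        (sid, chao1(row.to_numpy()), shannon(row.to_numpy()))
        for sid, row in table.counts.iterrows()
    ]
    return pd.DataFrame(rows, columns=["sample_id", "chao1", "shannon"])


def bray_curtis(table: Union[OtuTable, pd.DataFrame]) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = 1 - 2*sum(min)/sum(x+y)."""
    df = table.counts if isinstance(table, OtuTable) else table
    if df.shape[0] < 2:
        raise ValueError("need at least two samples")
    totals = df.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    return beta_diversity(
        "braycurtis", df.to_numpy(dtype=float), ids=list(df.index.astype(str))
    )


@dataclass
class OrdinationResult:
    """Classical-scaling ordination: sample coordinates on the positive
    axes, the full descending eigenvalue spectrum, and per-axis explained
    fractions (negative eigenvalues excluded from the denominator)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis by eigendecomposition of the
    double-centered squared-distance matrix (Gower centering)."""
    n = len(dist.ids)
    if n < 3:
        raise ValueError("PCoA needs at least three samples")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    axes = [f"PCo{i + 1}" for i in range(int(positive.sum()))]
    explained = eigvals[positive] / eigvals[positive].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=axes),
        eigenvalues=eigvals,
        explained_fraction=explained,
    )


def _non_uti(meta: Sequence[SampleRecord], ids) -> list[SampleRecord]:
    ids = set(ids)
    return [r for r in meta if r.visit is not Visit.UTI_EVENT and r.sample_id in ids]


def compare_within_between_subject(
    dist: DistanceMatrix, meta: Sequence[SampleRecord]
) -> tuple[float, float, float]:
    """Compare same-subject against different-subject pairwise distances.

    Returns (median_within, median_between, two-sided rank-sum p). All
    cross-subject pairs enter the between set; pair non-independence is
    accepted, matching the naive convention of such cohort comparisons.
    """
    records = _non_uti(meta, dist.ids)
    subject_of = {r.sample_id: r.subject_id for r in records}
    within, between = [], []
    ids = [sid for sid in dist.ids if sid in subject_of]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = float(dist[ids[i], ids[j]])
            if subject_of[ids[i]] == subject_of[ids[j]]:
                within.append(d)
            else:
                between.append(d)
    if not within:
        raise ValueError("no same-subject sample pairs in the distance matrix")
    p = wilcoxon_rank_sum(within, between)
    return float(np.median(within)), float(np.median(between)), p


def per_subject_shift(
    dist: DistanceMatrix, meta: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Per-subject Bray-Curtis distance between the week-0 and week-24
    samples, with the subject's arm."""
    records = _non_uti(meta, dist.ids)
    by_subject: dict[str, dict[Visit, str]] = {}
    arm_of = {}
    for r in records:
        by_subject.setdefault(r.subject_id, {})[r.visit] = r.sample_id
        arm_of[r.subject_id] = r.arm
    rows = []
    for subject, visits in by_subject.items():
        if Visit.WEEK0 in visits and Visit.WEEK24 in visits:
            d = float(dist[visits[Visit.WEEK0], visits[Visit.WEEK24]])
            rows.append((subject, arm_of[subject].value, d))
    return pd.DataFrame(rows, columns=["subject_id", "arm", "shift"])


def compare_shift_magnitude(
    dist: DistanceMatrix, meta: Sequence[SampleRecord]
) -> tuple[float, float, float]:
    """Compare the magnitude of the week0->week24 community shift between
    study arms. Returns (median_shift_cranberry, median_shift_placebo, p)."""
    shifts = per_subject_shift(dist, meta)
    cran = shifts.loc[shifts.arm == "cranberry", "shift"].to_numpy()
    plac = shifts.loc[shifts.arm == "placebo", "shift"].to_numpy()
    if len(cran) < 2 or len(plac) < 2:
        raise ValueError(
            "each arm needs at least two subjects with both week0 and week24 samples"
        )
    p = wilcoxon_rank_sum(cran, plac)
    return float(np.median(cran)), float(np.median(plac)), p
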