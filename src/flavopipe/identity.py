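"""Average nucleotide identity between a reference genome and conspecific
sequence inside a metagenomic sample.

Per-position calls (reference/variant allele, summed base quality, high-
quality depth) from an upstream aligner+caller are filtered — minimum
summed base quality, then removal of depth outliers more than k standard
deviations above the mean depth, which flags cross-mapping from homologous
sequence of more abundant organisms — and the ANI is the fraction of
passing calls that agree with the reference. Also here: breadth of
coverage, a coverage-ratio estimate of 16S copy number, and the
orthogroup-mean pairwise ANI used between assembled genomes.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .types import AniEstimate, CallFilterConfig, PositionCall

SPECIES_ANI_CUTOFF = 0.95


def filter_calls(
    calls: Sequence[PositionCall], cfg: Optional[CallFilterConfig] = None
) -> list[PositionCall]:
    """Apply the quality-sum and depth-outlier filters.

    Calls with quality_sum below ``cfg.min_quality_sum`` are removed first;
    the depth mean and population SD are then computed over the survivors
    and calls with depth strictly above mean + multiplier*SD are dropped.
    """
    cfg = cfg or CallFilterConfig()
    if len(calls) == 0:
        raise ValueError("no calls supplied")
    quality_passing = [c for c in calls if c.quality_sum >= cfg.min_quality_sum]
    if not quality_passing:
        raise ValueError("no call passes the quality-sum filter")
    depths = np.array([c.depth for c in quality_passing], dtype=float)
    cutoff = depths.mean() + cfg.depth_sd_multiplier * depths.std(ddof=0)
    return [c for c in quality_passing if c.depth <= cutoff]


def estimate_ani(
    passing_calls: Sequence[PositionCall],
    reference_length: Optional[int] = None,
) -> AniEstimate:
    """ANI = 1 - (variant calls / passing calls); breadth is the fraction
    of reference positions with a passing call when the length is given."""
    n_passing = len(passing_calls)
    if n_passing == 0:
        raise ValueError("need at least one passing call")
    n_variant = sum(1 for c in passing_calls if c.is_variant)
    breadth = None
    if reference_length is not None:
        if reference_length < n_passing:
            raise ValueError("reference length smaller than number of calls")
        breadth = len({c.position for c in passing_calls}) / reference_length
    return AniEstimate(
        ani=1.0 - n_variant / n_passing,
        n_passing=n_passing,
        n_variant=n_variant,
        breadth=breadth,
    )


def species_boundary(ani: float) -> str:
    """Classify an ANI value against the conventional 95% species cutoff
    (inclusive): 'same_species' iff ani >= 0.95."""
    if not 0.0 <= ani <= 1.0:
        raise ValueError("ANI must be in [0, 1]")
    return "same_species" if ani >= SPECIES_ANI_CUTOFF else "different_species"


def estimate_16s_copy_number(
    locus_mean_depth: float, genome_median_depth: float
) -> float:
    """Copy number of a locus from its mean coverage relative to the
    genome-wide median coverage."""
    if genome_median_depth <= 0:
        raise ValueError("genome median depth must be positive")
    if locus_mean_depth < 0:
        raise ValueError("locus depth must be non-negative")
    return locus_mean_depth / genome_median_depth


def orthogroup_ani(
    aligned_pairs: Sequence[tuple[str, str]], per_position: bool = False
) -> float:
    """Mean pairwise identity over per-orthogroup alignments.

    Each pair is a gapped equal-length alignment of the two genomes' genes
    from one orthogroup; identity is counted over columns where neither
    sequence is gapped. The default averages identities unweighted across
    orthogroups; ``per_position=True`` pools identical/compared columns
    over all orthogroups instead.
    """
    if len(aligned_pairs) == 0:
        raise ValueError("need at least one aligned orthogroup pair")
    identities = []
    total_match = total_cols = 0
    for idx, (seq_a, seq_b) in enumerate(aligned_pairs):
        if len(seq_a) != len(seq_b):
            raise ValueError(f"orthogroup {idx}: aligned sequences differ in length")
        a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
        b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
        comparable = (a != b"-") & (b != b"-")
        n_cols = int(comparable.sum())
        if n_cols == 0:
            warnings.warn(f"orthogroup {idx} has no comparable columns; skipped")
            continue
        n_match = int((a[comparable] == b[comparable]).sum())
        identities.append(n_match / n_cols)
        total_match += n_match
        total_cols += n_cols
    if not identities:
        raise ValueError("every orthogroup pair was skipped (no comparable columns)")
    if per_position:
        return total_match / total_cols
    return float(np.mean(identities))


def cohort_ani_summary(
    estimates: dict[str, AniEstimate],
    min_breadth: float = CallFilterConfig().min_breadth_for_report,
) -> dict[str, float]:
    """Median and range of per-sample ANI over samples whose breadth meets
    the reporting threshold (default: at least half the genome confidently
    covered)."""
    kept = {
        s: e
        for s, e in estimates.items()
        if e.breadth is not None and e.breadth >= min_breadth
    }
    if not kept:
        raise ValueError("no sample meets the breadth threshold")
    values = np.array([e.ani for e in kept.values()])
    return {
        "n_samples": len(kept),
        "median_ani": float(np.median(values)),
        "min_ani": float(values.min()),
        "max_ani": float(values.max()),
    }
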