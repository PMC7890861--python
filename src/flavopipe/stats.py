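"""Shared statistical primitives: rank-sum test, BH correction, Fisher exact.

These wrap scipy/statsmodels with the conventions used throughout the
pipeline: two-sided tests, exact enumeration for small tie-free groups,
midrank/tie-corrected normal approximation otherwise, step-up FDR control.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_GROUP = 8
_ENUMERATION_LIMIT = 500_000  # C(n, k) cap for forced-exact enumeration


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def _exact_midrank_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group labelings of the
    pooled midranks. Used when an exact p is requested despite ties."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    if math.comb(len(pooled), n1) > _ENUMERATION_LIMIT:
        raise ValueError(
            "exact enumeration infeasible for these group sizes; use mode='approx'"
        )
    ranks = sps.rankdata(pooled)
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mean)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mean) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode='auto'`` uses the exact null distribution when the smaller group
    has at most 8 observations and the pooled data are tie-free; otherwise
    the normal approximation with midranks, tie-corrected variance and
    continuity correction. ``'exact'`` forces exact (enumerating labelings
    of midranks under ties); ``'approx'`` forces the approximation.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in {"auto", "exact", "approx"}:
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ties = _has_ties(pooled)
    if mode == "exact" or (
        mode == "auto" and min(x.size, y.size) <= EXACT_MAX_GROUP and not ties
    ):
        if ties:
            return _exact_midrank_p(x, y)
        return float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    p = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    ).pvalue
    return float(min(p, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p) where the odds ratio is the sample
    (cross-product) estimate a*d / (b*c) and the two-sided p sums all
    hypergeometric tables at most as probable as the observed one.
    """
    for v in (a, b, c, d):
        if not float(v).is_integer() or v < 0:
            raise ValueError("table cells must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("contingency table is all zero")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
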