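"""Independent brute-force oracles used to verify the statistical primitives.

These deliberately avoid scipy/statsmodels: the rank-sum oracle enumerates
group labelings of midranks, the Fisher oracle enumerates hypergeometric
tables with exact rational arithmetic, and the BH oracle applies the
step-up formula directly.
"""

import itertools
import math
from fractions import Fraction


def rank_sum_p_enumerated(x, y) -> float:
    """Two-sided rank-sum p by full enumeration over labelings (midranks)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    # midranks without scipy
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    observed = sum(ranks[:n1])
    mean = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mean)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[k] for k in combo) - mean) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def fisher_p_enumerated(a, b, c, d) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed
    margins and summing probabilities <= the observed table's."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(k: int) -> Fraction:
        return Fraction(
            math.comb(row1, k) * math.comb(row2, col1 - k), math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    observed = table_prob(a)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        p = table_prob(k)
        if p <= observed:
            total += p
    return float(total)


def bh_step_up(pvals) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the step-up formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(pvals[idx] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted
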