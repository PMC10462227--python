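"""Brute-force reference implementations used as self-check oracles.

These deliberately share no code with the production paths in
:mod:`myelomap.diff`: the rank-sum p comes from explicit enumeration of
group assignments, BH from the literal step-up definition, and the
Fisher p from hypergeometric enumeration over all tables with the
observed margins.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import scipy.stats


def ranksum_enumeration_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = x.size
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    observed = ranks[:n1].sum()
    sums = [sum(c) for c in combinations(ranks, n1)]
    total = len(sums)
    eps = 1e-9
    lower = sum(1 for s in sums if s <= observed + eps) / total
    upper = sum(1 for s in sums if s >= observed - eps) / total
    return min(1.0, 2.0 * min(lower, upper))


def bh_step_up_reference(p_values) -> np.ndarray:
    """BH adjusted p-values by the literal step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(aa: int) -> float:
        return comb(row1, aa) * comb(row2, col1 - aa) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(aa)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)
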