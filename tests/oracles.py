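"""Independent brute-force oracles used to pin the statistical primitives.

These deliberately avoid the code paths they check: the Fisher oracle is a
direct hypergeometric enumeration over all tables with the observed margins,
and the rank-sum oracle enumerates every assignment of the pooled sample to
the two groups.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins.

    Orientation: rows (drug, others) x columns (target, non-target), i.e. the
    table [[a, c], [b, d]].  The p-value is the sum of the hypergeometric
    probabilities of all tables no more probable than the observed one
    (with a tiny relative tolerance against ties in floating point).
    """
    n = a + b + c + d
    row1 = a + c          # rows naming the drug
    col1 = a + b          # target-event rows
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    denom = comb(n, col1)
    probs = np.array([
        comb(row1, k) * comb(n - row1, col1 - k) / denom
        for k in range(lo, hi + 1)
    ])
    p_obs = probs[a - lo]
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def ranksum_two_sided_enumeration(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments.

    Requires an untied pooled sample.  Uses the U statistic; the two-sided
    p is the fraction of assignments at least as extreme (in either tail)
    as the observed U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires untied data"
    n1, n2 = len(x), len(y)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_min_obs = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    all_ranks = np.arange(1, n1 + n2 + 1)
    for idx in combinations(range(n1 + n2), n1):
        u = all_ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if u <= u_min_obs + 1e-9 or u >= n1 * n2 - u_min_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def corrected_ror_by_hand(a, b, c, d):
    """Cross-product ratio on half-corrected cells, written out longhand."""
    a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)
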