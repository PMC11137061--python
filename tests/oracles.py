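"""Independent brute-force oracles used to check the analysis code.

Everything here is deliberately written from first principles (integer
arithmetic, exhaustive enumeration, closed forms) and shares no code with
the implementation under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from evoreseq.containers import GT_HET, GT_MISSING


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact integer enumeration.

    All tables sharing the observed margins are enumerated; probability
    masses are compared as exact integers (numerators over the common
    denominator C(N, c1)), so tie handling is exact.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(kmin, kmax + 1)]
    n_obs = nums[a - kmin]
    return sum(v for v in nums if v <= n_obs) / denom


def fisher_oracle_margin(n_total: int, r1: int, c1: int):
    """All two-sided p-values for tables with margins (r1, n-r1; c1, n-c1).

    Returns (ks, ps): the support of the first cell and the p for each.
    Probability masses are compared as exact integers.
    """
    r2 = n_total - r1
    denom = comb(n_total, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    ks = list(range(kmin, kmax + 1))
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in ks]
    order = sorted(range(len(nums)), key=lambda i: nums[i])
    sorted_nums = [nums[i] for i in order]
    prefix = np.cumsum(sorted_nums)
    ps = [0.0] * len(ks)
    for rank, i in enumerate(order):
        # include every table whose mass is <= this one's (exact ties too)
        j = rank
        while j + 1 < len(order) and sorted_nums[j + 1] == sorted_nums[rank]:
            j += 1
        ps[i] = float(prefix[j]) / denom
    return ks, ps


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def ranksum_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Requires tie-free pooled data.  The two-sided p is twice the smaller
    tail of the exact U distribution, capped at 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in combinations(range(len(pooled)), n):
        grp = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in grp]
        us.append(sum(1 for xi in a for yj in b if xi > yj))
    total = len(us)
    le = sum(1 for u in us if u <= u_obs) / total
    ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(le, ge))


def private_mutations_brute_force(matrix, min_support: int = 3) -> np.ndarray:
    """Exhaustive sites x individuals scan for private minor alleles."""
    counts = np.zeros(matrix.n_individuals, dtype=np.int64)
    for s in range(matrix.n_sites):
        for i in range(matrix.n_individuals):
            if matrix.gt[s, i] != GT_HET:
                continue
            others = [
                matrix.gt[s, j]
                for j in range(matrix.n_individuals)
                if j != i and matrix.gt[s, j] != GT_MISSING
            ]
            if not others:
                continue
            # i's alt copy is the only one anywhere -> alt is the minor allele
            if all(g == 0 for g in others):
                support = matrix.alt_reads[s, i]
            # i's ref copy is the only one anywhere -> ref is the minor allele
            elif all(g == 2 for g in others):
                support = matrix.ref_reads[s, i]
            else:
                continue
            if support >= min_support:
                counts[i] += 1
    return counts


def ols_slope_oracle(x, y) -> float:
    """Closed-form simple-regression slope sum((x-xb)(y-yb)) / sum((x-xb)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())
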