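"""Independent reference implementations used only as test oracles.

These are deliberately written with different algorithms from the package:
a plain Gotoh dynamic program for local alignment scores, and brute-force
itertools enumerations for the exact Wilcoxon null distributions.
"""

from __future__ import annotations

import itertools

from scipy.stats import rankdata


def gotoh_local_score(
    query: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    first_gap: float = 7.0,
    extend_gap: float = 2.0,
) -> float:
    """Optimal local alignment score with affine gaps (gap of L costs 5+2L)."""
    nq, nr = len(query), len(reference)
    NEG = float("-inf")
    best = 0.0
    h_prev = [0.0] * (nr + 1)
    e_prev = [NEG] * (nr + 1)
    for i in range(1, nq + 1):
        h_cur = [0.0] * (nr + 1)
        e_cur = [NEG] * (nr + 1)
        f = NEG
        for j in range(1, nr + 1):
            qc, rc = query[i - 1], reference[j - 1]
            s = match if (qc == rc and qc != "N") else mismatch
            e_cur[j] = max(h_prev[j] - first_gap, e_prev[j] - extend_gap)
            f = max(h_cur[j - 1] - first_gap, f - extend_gap)
            h_cur[j] = max(0.0, h_prev[j - 1] + s, e_cur[j], f)
            best = max(best, h_cur[j])
        h_prev, e_prev = h_cur, e_cur
    return best


def rank_sum_p_enumeration(x, y, alternative: str = "two_sided") -> float:
    """Exact rank-sum p by enumerating every group assignment."""
    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n, k = len(pooled), len(x)
    observed = sum(ranks[: len(x)])
    lo = hi = total = 0
    for combo in itertools.combinations(range(n), k):
        s = sum(ranks[i] for i in combo)
        total += 1
        if s <= observed + 1e-12:
            lo += 1
        if s >= observed - 1e-12:
            hi += 1
    p_low, p_high = lo / total, hi / total
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(p_low, p_high))
    return p_low if alternative == "less" else p_high


def signed_rank_p_enumeration(diffs, alternative: str = "two_sided") -> float:
    """Exact signed-rank p by enumerating every sign pattern (zeros dropped)."""
    nonzero = [d for d in diffs if d != 0]
    if not nonzero:
        return 1.0
    ranks = rankdata([abs(d) for d in nonzero])
    m = len(nonzero)
    observed = sum(r for d, r in zip(nonzero, ranks) if d > 0)
    lo = hi = 0
    for signs in itertools.product([0, 1], repeat=m):
        s = sum(r for bit, r in zip(signs, ranks) if bit)
        if s <= observed + 1e-12:
            lo += 1
        if s >= observed - 1e-12:
            hi += 1
    total = 2**m
    p_low, p_high = lo / total, hi / total
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(p_low, p_high))
    return p_low if alternative == "less" else p_high
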