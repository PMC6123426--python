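"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain Python loops that
follow the definitions step by step.
"""

from __future__ import annotations

import math


def brute_force_es(genes, scores, member_set, weight_p=1.0):
    """Running-sum enrichment score by direct definition.

    Walk the list position by position; hits add |score|^p / sum_hits,
    misses subtract 1/(N - N_hit); return the running value with the
    largest absolute deviation from zero (first such position on ties).
    """
    n = len(genes)
    hits = [g in member_set for g in genes]
    n_hit = sum(hits)
    if n_hit == 0:
        raise ValueError("no members in list")
    denom = math.fsum(
        abs(s) ** weight_p for s, h in zip(scores, hits) if h
    )
    if denom == 0.0:
        raise ValueError("all member scores zero")
    miss_step = 0.0 if n == n_hit else 1.0 / (n - n_hit)
    running = 0.0
    best = 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            running += abs(s) ** weight_p / denom
        else:
            running -= miss_step
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_rank_es(genes, member_set):
    """Kolmogorov-Smirnov style (p = 0) score ignoring score magnitudes."""
    n = len(genes)
    n_hit = sum(1 for g in genes if g in member_set)
    if n_hit == 0:
        raise ValueError("no members in list")
    miss_step = 0.0 if n == n_hit else 1.0 / (n - n_hit)
    running = 0.0
    best = 0.0
    for g in genes:
        if g in member_set:
            running += 1.0 / n_hit
        else:
            running -= miss_step
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_bh(p_values):
    """Step-up BH by definition: q_(i) = min_{j >= i} (m / j) * p_(j)."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(indexed):
        best = math.inf
        for later_pos in range(rank_pos, m):
            j = later_pos + 1
            best = min(best, m / j * p_values[indexed[later_pos]])
        q[i] = min(best, 1.0)
    return q


def pearson_r(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
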