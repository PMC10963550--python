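"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written as plain loops from the mathematical
definitions, sharing no code with the package.
"""

from __future__ import annotations

import math


def ssgsea_oracle(values: dict[str, float], gene_set: set[str], alpha: float) -> float:
    """Enrichment score by direct ECDF-difference summation.

    Ranks 1..N ascending in expression (average on ties), walk genes in
    decreasing rank order (ties keep input order), accumulate the weighted
    in-set ECDF minus the unweighted out-of-set ECDF.
    """
    genes = list(values)
    n = len(genes)
    # Average ranks, computed pedestrian-style.
    ranks: dict[str, float] = {}
    for g in genes:
        below = sum(1 for h in genes if values[h] < values[g])
        equal = sum(1 for h in genes if values[h] == values[g])
        ranks[g] = below + (equal + 1) / 2.0

    order = sorted(range(n), key=lambda i: (-ranks[genes[i]], i))
    in_set = [genes[i] in gene_set for i in order]
    n_in = sum(in_set)
    assert 0 < n_in < n

    denom_in = sum(ranks[genes[i]] ** alpha for i in order if genes[i] in gene_set)
    p_in = 0.0
    p_out = 0.0
    es = 0.0
    for pos, i in enumerate(order):
        if in_set[pos]:
            p_in += ranks[genes[i]] ** alpha / denom_in
        else:
            p_out += 1.0 / (n - n_in)
        es += p_in - p_out
    return es


def logrank_oracle(
    times_a: list[float],
    events_a: list[int],
    times_b: list[float],
    events_b: list[int],
) -> tuple[float, float]:
    """Two-group log-rank chi-square and p by direct tabulation."""
    from scipy.stats import chi2 as chi2_dist

    data = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in data if e == 1})

    observed_minus_expected = 0.0
    variance = 0.0
    for t in event_times:
        n_at_risk = sum(1 for time, _, _ in data if time >= t)
        n_a = sum(1 for time, _, g in data if time >= t and g == 0)
        d = sum(1 for time, e, _ in data if time == t and e == 1)
        d_a = sum(1 for time, e, g in data if time == t and e == 1 and g == 0)
        expected_a = d * n_a / n_at_risk
        observed_minus_expected += d_a - expected_a
        if n_at_risk > 1:
            variance += (
                d
                * (n_a / n_at_risk)
                * (1 - n_a / n_at_risk)
                * (n_at_risk - d)
                / (n_at_risk - 1)
            )
    chi2 = observed_minus_expected**2 / variance
    p = float(chi2_dist.sf(chi2, df=1))
    return chi2, p


def ranksum_exact_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumeration (tiny n, no ties)."""
    from itertools import combinations

    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n_a = len(a)

    def u_stat(group_a: tuple[float, ...]) -> float:
        rest = [x for x in pooled if x not in group_a]
        return sum(1 for x in group_a for y in rest if x > y)

    observed = u_stat(tuple(a))
    center = n_a * (len(b)) / 2.0
    dev = abs(observed - center)
    count = 0
    total = 0
    for combo in combinations(pooled, n_a):
        total += 1
        if abs(u_stat(combo) - center) >= dev - 1e-12:
            count += 1
    return count / total
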