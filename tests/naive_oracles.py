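"""Independent brute-force reference implementations used only by tests.

Deliberately written as explicit per-element loops over the raw data, a
different route from the vectorised package code they check.
"""

from __future__ import annotations

import itertools
import math


def naive_km(times, events):
    """Product-limit estimator via explicit per-sample counting.

    Returns (event_times, survival) as python lists.
    """
    data = sorted(zip(list(times), list(events)))
    event_times = sorted({t for t, e in data if e == 1})
    surv = []
    s = 1.0
    for et in event_times:
        n_at_risk = 0
        d = 0
        for t, e in data:
            if t >= et:
                n_at_risk += 1
            if t == et and e == 1:
                d += 1
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return event_times, surv


def naive_logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank via explicit hypergeometric tables.

    Returns (chi2, z) with z signed for group a.
    """
    a = list(zip(list(times_a), list(events_a)))
    b = list(zip(list(times_b), list(events_b)))
    event_times = sorted({t for t, e in a + b if e == 1})
    O_a = sum(e for _, e in a)
    E_a = 0.0
    V = 0.0
    for et in event_times:
        n_a = sum(1 for t, _ in a if t >= et)
        n_b = sum(1 for t, _ in b if t >= et)
        d_a = sum(1 for t, e in a if t == et and e == 1)
        d_b = sum(1 for t, e in b if t == et and e == 1)
        n = n_a + n_b
        d = d_a + d_b
        E_a += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    z = (O_a - E_a) / math.sqrt(V)
    return z * z, z


def naive_bh(pvals):
    """Step-up BH: sort, scale by n/rank, cumulative min from the top."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        adj[i] = running
    return adj


def naive_hypergeom_tail(universe, gene_set, query):
    """P(overlap >= observed) by exhaustive enumeration of all draws."""
    universe = sorted(universe)
    members = set(gene_set) & set(universe)
    q = set(query) & set(universe)
    observed = len(q & members)
    hits = total = 0
    for draw in itertools.combinations(universe, len(q)):
        total += 1
        if len(set(draw) & members) >= observed:
            hits += 1
    return hits / total


def naive_spearman(x, y):
    """Rank (average ties) by hand, then Pearson by the definition."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
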