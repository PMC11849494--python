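"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a statistic by direct enumeration, independently of the
package's implementation paths.
"""

import math
from itertools import combinations


def logrank_oracle(time_a, event_a, time_b, event_b):
    """Event-table enumeration of the two-group log-rank statistic.

    Walks the distinct event times, accumulating observed and expected events
    for group A and the hypergeometric variance term by term.
    Returns (chi-square statistic, signed z for group A).
    """
    ta, ea = list(map(float, time_a)), list(map(int, event_a))
    tb, eb = list(map(float, time_b)), list(map(int, event_b))
    event_times = sorted(
        {t for t, e in zip(ta + tb, ea + eb) if e == 1}
    )
    O = E = V = 0.0
    for t in event_times:
        n_a = sum(1 for x in ta if x >= t)
        n_b = sum(1 for x in tb if x >= t)
        d_a = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        n, d = n_a + n_b, d_a + d_b
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n - d) / (n - 1) * (n_a / n) * (1 - n_a / n)
    z = (O - E) / math.sqrt(V)
    return z * z, z


def km_oracle(times_events):
    """Hand product-limit computation: list of (time, event) -> [(t, S(t))]."""
    pts = sorted(times_events)
    out = []
    s = 1.0
    event_times = sorted({t for t, e in pts if e == 1})
    for t in event_times:
        at_risk = sum(1 for x, _ in pts if x >= t)
        d = sum(1 for x, e in pts if x == t and e == 1)
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


def ari_oracle(labels_a, labels_b):
    """Adjusted Rand index by exhaustive pair enumeration."""
    n = len(labels_a)
    pairs = list(combinations(range(n), 2))
    same_both = sum(
        1 for i, j in pairs if labels_a[i] == labels_a[j] and labels_b[i] == labels_b[j]
    )
    same_a = sum(1 for i, j in pairs if labels_a[i] == labels_a[j])
    same_b = sum(1 for i, j in pairs if labels_b[i] == labels_b[j])
    total = len(pairs)
    expected = same_a * same_b / total
    maximum = 0.5 * (same_a + same_b)
    if maximum == expected:
        return 1.0
    return (same_both - expected) / (maximum - expected)


def gsea_es_oracle(metric, hit_positions, weight=0.0):
    """Exhaustive running-sum enumeration of the enrichment score."""
    n = len(metric)
    hits = set(hit_positions)
    nh = len(hits)
    wsum = sum(abs(metric[i]) ** weight for i in hits)
    run, best = 0.0, 0.0
    for i in range(n):
        if i in hits:
            run += abs(metric[i]) ** weight / wsum
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def bh_oracle(pvalues):
    """Step-up BH by hand: sort, scale by n/rank, enforce monotonicity."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q


def spearman_oracle(x, y):
    """Tie-corrected Spearman as Pearson on average ranks, by direct formula."""

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
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
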