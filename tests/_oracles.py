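"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration, deliberately ignoring the
vectorized implementations under test.
"""

from __future__ import annotations

import math

import numpy as np

TIE_TOL = 1e-9


def km_brute(times, events):
    """Product-limit estimate by explicit risk-set enumeration.

    Returns (event_times, survival_after_each_event_time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ts = sorted(set(times[events == 1]))
    s = 1.0
    out = []
    for t in ts:
        n_at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1.0 - d / n_at_risk
        out.append(s)
    return np.array(ts), np.array(out)


def logrank_brute(times, events, member1):
    """Two-group log-rank by explicit risk-table enumeration.

    ``member1`` is a boolean array marking group 1.  Returns
    (statistic, O1, E1, V).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    member1 = np.asarray(member1, dtype=bool)
    o1 = e1 = v = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & member1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & member1).sum())
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = (o1 - e1) ** 2 / v if v > 0 else math.nan
    return stat, o1, e1, v


def cutpoint_brute(values, times, events, min_frac=0.1):
    """Exhaustive cut-point search over midpoints of consecutive distinct
    values, with the documented tie-breaking (balance, then smaller tau)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    distinct = np.unique(values)
    mids = [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    min_n = math.ceil(min_frac * n)
    results = []
    for tau in mids:
        high = values > tau
        if high.sum() < min_n or (n - high.sum()) < min_n:
            continue
        stat, *_ = logrank_brute(times, events, high)
        if not math.isnan(stat):
            results.append((tau, stat, abs(n - 2 * int(high.sum()))))
    if not results:
        return None
    best = max(stat for _, stat, _ in results)
    tied = [r for r in results if r[1] >= best - TIE_TOL]
    tied.sort(key=lambda r: (r[2], r[0]))
    tau, stat, _ = tied[0]
    return tau, stat


def chi2_2x2_closed(a, b, c, d):
    """Pearson chi-square of a 2x2 table [[a, b], [c, d]], closed form
    n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


def chi2_table_brute(table):
    """Pearson chi-square of any contingency table by sum (O-E)^2/E."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


def cronbach_brute(items):
    """Cronbach's alpha from a brute-force covariance computation."""
    x = np.asarray(items, dtype=float)
    n, k = x.shape
    item_vars = [np.var(x[:, i], ddof=1) for i in range(k)]
    totals = x.sum(axis=1)
    total_var = np.var(totals, ddof=1)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


def kruskal_2group_brute(a, b):
    """Kruskal-Wallis chi-square approximation for two groups via explicit
    mid-rank sums and the tie correction."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r_a = ranks[: a.size].sum()
    r_b = ranks[a.size :].sum()
    h = 12.0 / (n * (n + 1)) * (r_a**2 / a.size + r_b**2 / b.size) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie_corr
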