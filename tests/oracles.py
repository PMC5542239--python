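"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive each statistic from first principles, without
touching the package implementations they check.
"""

from __future__ import annotations

import math


def km_brute_force(times, events):
    """Product-limit survival as a list of (event_time, S) pairs.

    Walks distinct event times in order; at each, S is multiplied by
    (n - d) / n with n = subjects whose time is >= t (events at tied times
    counted before censorings by this risk-set definition).
    """
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e == 1})
    s = 1.0
    out = []
    for t in event_times:
        n = sum(1 for tt, _ in pairs if tt >= t)
        d = sum(1 for tt, ee in pairs if tt == t and ee == 1)
        s *= (n - d) / n
        out.append((t, s))
    return out


def km_at(times, events, horizon):
    s = 1.0
    for t, s_t in km_brute_force(times, events):
        if t <= horizon:
            s = s_t
    return s


def logrank_two_group_brute_force(groups, times, events):
    """Two-group log-rank chi-square via the O-E / V tally for group 0."""
    labels = sorted(set(groups))
    assert len(labels) == 2
    g0 = labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        n = sum(1 for tt in times if tt >= t)
        d = sum(1 for tt, ee in zip(times, events) if tt == t and ee == 1)
        n0 = sum(1 for tt, gg in zip(times, groups) if tt >= t and gg == g0)
        d0 = sum(
            1 for tt, ee, gg in zip(times, events, groups) if tt == t and ee == 1 and gg == g0
        )
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n0 / n) * (1 - n0 / n)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def fisher_exact_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_fact(k):
        return math.lgamma(k + 1)

    def log_p(x):
        # P(X = x) for X ~ Hypergeom(n, row1, col1)
        return (
            log_fact(row1) - log_fact(x) - log_fact(row1 - x)
            + log_fact(row2) - log_fact(col1 - x) - log_fact(row2 - (col1 - x))
            - (log_fact(n) - log_fact(col1) - log_fact(n - col1))
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p_x = math.exp(log_p(x))
        if p_x <= p_obs * (1 + 1e-9):
            total += p_x
    return min(total, 1.0)


def binom_two_sided_p(k, n, p=0.5):
    """Exact two-sided binomial p-value by enumeration (small n only)."""
    def pmf(x):
        return math.comb(n, x) * p**x * (1 - p) ** (n - x)

    p_obs = pmf(k)
    return sum(pmf(x) for x in range(n + 1) if pmf(x) <= p_obs * (1 + 1e-12))
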