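"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (plain Python loops, closed forms,
pairwise enumeration) and shares no code with the implementation.
"""

from __future__ import annotations

import math


def brute_force_step(values):
    """Exhaustive single-step fit: returns (k, mu_low, mu_high, sse).

    Evaluates every split of the ascending-sorted values with sequential
    float accumulation; first minimum wins.
    """
    x = sorted(float(v) for v in values)
    n = len(x)
    best = None
    for k in range(1, n):
        mu_lo = sum(x[:k]) / k
        mu_hi = sum(x[k:]) / (n - k)
        fitted = [mu_lo] * k + [mu_hi] * (n - k)
        sse = 0.0
        for xi, fi in zip(x, fitted):
            d = xi - fi
            sse += d * d
        if best is None or sse < best[3]:
            best = (k, mu_lo, mu_hi, sse)
    return best


def brute_force_step_statistic(values, dof):
    """Regression statistic recomputed from scratch via the brute fit."""
    x = sorted(float(v) for v in values)
    n = len(x)
    _, _, _, sse_step = brute_force_step(values)
    mean = sum(x) / n
    sse_null = 0.0
    for xi in x:
        d = xi - mean
        sse_null += d * d
    if sse_null == sse_step:
        return 0.0
    if sse_step == 0.0:
        return float("inf")
    return ((sse_null - sse_step) / (dof - 1)) / (sse_step / (n - dof))


def auc_by_enumeration(scores, labels, positive):
    """AUC as the average over all positive-negative pairs (ties 0.5)."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_step_up(pvals):
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def welch_t(a, b):
    """Welch t statistic and two-sided p from the textbook formulas."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p


def hypergeom_upper_tail(overlap, n_universe, n_set, n_hits):
    """P(X >= overlap) by summing the closed-form pmf."""
    total = 0.0
    for k in range(overlap, min(n_set, n_hits) + 1):
        total += (
            math.comb(n_set, k)
            * math.comb(n_universe - n_set, n_hits - k)
            / math.comb(n_universe, n_hits)
        )
    return total


def ols_normal_equations(x_rows, y):
    """Least-squares coefficients via the normal equations."""
    import numpy as np

    x = np.asarray(x_rows, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(x.T @ x, x.T @ y)


def logrank_observed_expected(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square by explicit per-event-time tallies."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in records if e})
    obs_a = 0.0
    exp_a = 0.0
    var = 0.0
    for t in event_times:
        at_risk_a = sum(1 for ti, _, g in records if ti >= t and g == 0)
        at_risk_b = sum(1 for ti, _, g in records if ti >= t and g == 1)
        n = at_risk_a + at_risk_b
        d = sum(1 for ti, e, _ in records if ti == t and e)
        d_a = sum(1 for ti, e, g in records if ti == t and e and g == 0)
        obs_a += d_a
        exp_a += d * at_risk_a / n
        if n > 1:
            var += (
                d * (at_risk_a / n) * (at_risk_b / n) * (n - d) / (n - 1)
            )
    if var == 0:
        return 0.0
    return (obs_a - exp_a) ** 2 / var


def km_product_limit(times, events):
    """Kaplan-Meier survival at each distinct event time, naive product."""
    event_times = sorted({t for t, e in zip(times, events) if e})
    surv = []
    s = 1.0
    for t in event_times:
        n = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, e in zip(times, events) if ti == t and e)
        s *= 1.0 - d / n
        surv.append((t, s))
    return surv
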