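"""Brute-force reference implementations used only as independent test oracles.

Each oracle re-derives its quantity from the definition with plain Python
loops, sharing no code with the package implementations.
"""
from __future__ import annotations

import numpy as np


def brute_segment(
    timestamps_ms, accel, speed_threshold, min_duration_ms=100.0, rest_accel=0.05
):
    """Naive scan: integrate speed with rest resets, list threshold runs.

    Returns a list of (start_index, end_index) inclusive pairs.
    """
    t = list(timestamps_ms)
    a = list(accel)
    n = len(t)
    v = [0.0] * n
    for i in range(1, n):
        if abs(a[i]) < rest_accel:
            v[i] = 0.0
        else:
            v[i] = v[i - 1] + 0.5 * (a[i] + a[i - 1]) * (t[i] - t[i - 1]) / 1000.0
    episodes = []
    i = 0
    prev_end = -1
    while i < n:
        if v[i] >= speed_threshold:
            start = prev_end + 1
            for j in range(i, prev_end, -1):
                if v[j] == 0.0:
                    start = j
                    break
            end = i
            while end + 1 < n and v[end + 1] >= speed_threshold:
                end += 1
            if t[end] - t[start] >= min_duration_ms and end > start:
                episodes.append((start, end))
            prev_end = end
            i = end + 1
        else:
            i += 1
    return episodes


def brute_shakings(accel):
    """Exhaustive mound scan from the definition.

    Walk the segment, cutting it at every strict interior local minimum; for
    each resulting piece locate the peak by linear search and classify by the
    smaller flank, discarding boundary-peaked pieces.
    Returns a list of (level, start, peak, end).
    """
    a = list(accel)
    n = len(a)
    if n < 3:
        return []
    cuts = [0]
    for i in range(1, n - 1):
        if a[i] < a[i - 1] and a[i] < a[i + 1]:
            cuts.append(i)
    cuts.append(n - 1)
    events = []
    for b0, b1 in zip(cuts[:-1], cuts[1:]):
        peak = b0
        for j in range(b0, b1 + 1):
            if a[j] > a[peak]:
                peak = j
        left = peak - b0
        right = b1 - peak
        s = left if left < right else right
        if s == 0:
            continue
        events.append((min(s, 4), b0, peak, b1))
    return events


def brute_oneway_anova(matrix):
    """Mean squares of the one-way (targets) ANOVA via explicit double loops."""
    m = [list(row) for row in matrix]
    n = len(m)
    k = len(m[0])
    total = 0.0
    for row in m:
        for x in row:
            total += x
    grand = total / (n * k)
    ssb = 0.0
    ssw = 0.0
    for row in m:
        mean_i = sum(row) / k
        ssb += k * (mean_i - grand) ** 2
        for x in row:
            ssw += (x - mean_i) ** 2
    return ssb / (n - 1), ssw / (n * (k - 1))


def brute_ols(y, X):
    """Normal-equations OLS with explicit summations.

    Returns (coefficients incl. intercept first, standard errors, r_squared).
    """
    y = list(map(float, y))
    X = [[1.0, *map(float, row)] for row in np.atleast_2d(X)]
    n = len(y)
    p = len(X[0])
    xtx = [[sum(X[i][a] * X[i][b] for i in range(n)) for b in range(p)] for a in range(p)]
    xty = [sum(X[i][a] * y[i] for i in range(n)) for a in range(p)]
    beta = np.linalg.solve(np.array(xtx), np.array(xty))
    resid = [y[i] - sum(beta[a] * X[i][a] for a in range(p)) for i in range(n)]
    sse = sum(r * r for r in resid)
    ybar = sum(y) / n
    sst = sum((yi - ybar) ** 2 for yi in y)
    mse = sse / (n - p)
    cov = mse * np.linalg.inv(np.array(xtx))
    se = np.sqrt(np.diag(cov))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return beta, se, r2
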