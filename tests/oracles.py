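"""Independent brute-force reimplementations used as test oracles.

Everything here is written directly from the mathematical definitions with
plain Python loops, deliberately sharing no code with the package, so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math


def naive_moving_average(values, window: int) -> list:
    """Centered windowed mean, window clipped at the edges, by direct summation."""
    v = list(values)
    n = len(v)
    left = (window - 1) // 2
    right = window // 2
    out = []
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n - 1, i + right)
        chunk = v[lo:hi + 1]
        out.append(sum(chunk) / len(chunk))
    return out


def naive_sad_curve(values, N: int) -> list:
    sad = []
    for n in range(1, N + 1):
        filt = naive_moving_average(values, n)
        sad.append(sum(abs(a - b) for a, b in zip(values, filt)))
    return sad


def naive_gradient(values) -> list:
    """Central difference 0.5*(g[i+1]-g[i-1]) inside, one-sided at the ends."""
    g = list(values)
    n = len(g)
    out = [g[1] - g[0]]
    for i in range(1, n - 1):
        out.append(0.5 * (g[i + 1] - g[i - 1]))
    out.append(g[n - 1] - g[n - 2])
    return out


def naive_sign_scan(values) -> list:
    """Sign-change indices, zeros carrying the previous nonzero sign."""
    crossings = []
    carry = 0
    for i, x in enumerate(values):
        s = int(x > 0) - int(x < 0)
        if s == 0:
            continue
        if carry != 0 and s != carry:
            crossings.append(i)
        carry = s
    return crossings


def naive_pairwise_merge(points, min_gap: int = 3) -> list:
    """Left-to-right merge of points closer than min_gap to ceil of their mean."""
    if not points:
        return []
    out = []
    cur = points[0]
    for nxt in points[1:]:
        if nxt - cur < min_gap:
            cur = math.ceil((cur + nxt) / 2)
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def brute_select_windows(values, N: int, count: int = 3, min_gap: int = 3) -> list:
    """The whole selection pipeline, end to end, from the definitions."""
    sad = naive_sad_curve(values, N)
    g3 = naive_gradient(naive_gradient(naive_gradient(sad)))
    crossings = naive_sign_scan(g3)
    windows = [i + 1 for i in crossings]  # array index 0 <-> window length 1
    return naive_pairwise_merge(windows, min_gap)[:count]


def naive_periods(values, thr) -> list:
    """Maximal runs of values >= thr as (i_start, i_stop) inclusive pairs."""
    periods = []
    start = None
    for i, x in enumerate(values):
        if x >= thr:
            if start is None:
                start = i
        else:
            if start is not None:
                periods.append((start, i - 1))
                start = None
    if start is not None:
        periods.append((start, len(values) - 1))
    return periods
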