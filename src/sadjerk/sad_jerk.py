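"""SAD curve, third gradient (jerk), zero-crossings and window selection.

The core procedure: for every candidate window length ``n = 1..N`` compute
the sum of absolute differences (SAD) between the signal and its
moving-average-filtered version,

    SAD(n) = sum_i | x(i) - MA(x, n)(i) |,

then apply the discrete gradient three times to the SAD curve and report the
window lengths at which this third gradient ("jerk") changes sign.  The first
zero-point P1 is the conservative window choice, the second P2 the liberal
one; zero-points closer than a small gap are merged to the ceiling of their
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .smoothing import moving_average_values
from .timeseries_io import UniformSeries

__all__ = [
    "SADCurve",
    "JerkCurve",
    "ZeroPointSet",
    "compute_sad_curve",
    "discrete_gradient",
    "third_gradient",
    "find_zero_crossings",
    "merge_zero_points",
    "select_windows",
    "classic_flattening_window",
    "DEFAULT_MAX_WINDOW",
    "DEFAULT_MERGE_GAP",
]

DEFAULT_MAX_WINDOW = 250
DEFAULT_MERGE_GAP = 3


@dataclass(frozen=True)
class SADCurve:
    """SAD values indexed by moving-average window length ``1..N``."""

    windows: np.ndarray  # 1, 2, ..., N (samples)
    sad_values: np.ndarray
    sample_interval_s: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=int)
        s = np.asarray(self.sad_values, dtype=float)
        if w.size != s.size:
            raise ValueError("windows and sad_values must have equal length")
        if w.size == 0 or w[0] != 1 or np.any(np.diff(w) != 1):
            raise ValueError("windows must be 1..N with unit step")
        if np.any(s < 0):
            raise ValueError("SAD values cannot be negative")
        w.setflags(write=False)
        s.setflags(write=False)
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "sad_values", s)

    @property
    def N(self) -> int:
        return int(self.windows[-1])

    def to_csv(self, path) -> None:
        """Two-column CSV (window, sad) for external plotting."""
        np.savetxt(
            path,
            np.column_stack([self.windows, self.sad_values]),
            delimiter=",",
            header="window,sad",
            comments="",
            fmt=("%d", "%.12g"),
        )


@dataclass(frozen=True)
class JerkCurve:
    """Repeated discrete gradient of a SAD curve, aligned to its windows."""

    windows: np.ndarray
    values: np.ndarray
    order: int = 3

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.windows, self.values]),
            delimiter=",",
            header=f"window,gradient{self.order}",
            comments="",
            fmt=("%d", "%.12g"),
        )


@dataclass(frozen=True)
class ZeroPointSet:
    """Ordered candidate window lengths from jerk zero-crossings.

    ``points`` are window lengths in samples (seconds at a 1 s interval),
    after merging of close crossings and truncation to the requested count.
    ``merged_from`` records, for each point, the raw crossing windows that
    were combined into it.  ``complete`` is False when fewer than the
    requested number of crossings exist (e.g. a constant signal has none).
    """

    points: tuple
    merged_from: tuple = ()
    requested: int = 3
    complete: bool = True

    def __post_init__(self) -> None:
        pts = tuple(int(p) for p in self.points)
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValueError("zero-points must be strictly increasing")
        if any(p < 2 for p in pts):
            raise ValueError("a zero-crossing needs a predecessor: points must be >= 2")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def compute_sad_curve(series: UniformSeries, N: int = DEFAULT_MAX_WINDOW) -> SADCurve:
    """SAD between a series and its moving average, for windows ``1..N``.

    ``SAD(1) = 0`` exactly (window-1 filter is the identity) and every SAD of
    a constant series is 0: the curve measures how much smoothing each window
    applies to *this* signal.
    """
    N = int(N)
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if N > len(series):
        raise ValueError(f"N={N} exceeds series length {len(series)}")
    v = series.values
    sad = np.empty(N)
    sad[0] = 0.0
    for n in range(2, N + 1):
        sad[n - 1] = np.abs(v - moving_average_values(v, n)).sum()
    return SADCurve(np.arange(1, N + 1), sad, series.sample_interval_s)


def discrete_gradient(values) -> np.ndarray:
    """Discrete gradient at unit spacing.

    Interior points use the central difference ``0.5*(g[i+1] - g[i-1])``;
    the two endpoints use first-order one-sided differences.  Exact on linear
    sequences everywhere and on quadratics at interior points.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("gradient needs at least 2 values")
    return np.gradient(v)


def third_gradient(sad: SADCurve) -> JerkCurve:
    """Apply the discrete gradient three times to a SAD curve."""
    if sad.sad_values.size < 4:
        raise ValueError("SAD curve too short for a third gradient (need >= 4 points)")
    g3 = discrete_gradient(discrete_gradient(discrete_gradient(sad.sad_values)))
    return JerkCurve(sad.windows, g3, order=3)


def find_zero_crossings(values) -> list[int]:
    """Indices where a sequence changes sign, reported at the later index.

    A value that is exactly zero inherits the most recent nonzero sign, so a
    touch-and-return does not count as a crossing and a pass through zero
    counts exactly once (at the first index with the opposite sign).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to detect a crossing")
    crossings: list[int] = []
    carry = 0  # most recent nonzero sign seen
    for i, s in enumerate(np.sign(v)):
        if s == 0:
            continue
        if carry != 0 and s != carry:
            crossings.append(i)
        carry = int(s)
    return crossings


def merge_zero_points(indices, min_gap: int = DEFAULT_MERGE_GAP):
    """Merge zero-points closer than ``min_gap`` steps to the ceiling of their mean.

    Scanning left to right: whenever the next point lies fewer than
    ``min_gap`` steps from the current (possibly already-merged) point, the
    pair is replaced by ``ceil(mean)`` and the merged value re-enters the
    comparison with the following point.

    Returns ``(merged_points, merged_from)`` where ``merged_from[k]`` lists
    the raw input points combined into ``merged_points[k]``.
    """
    pts = [int(i) for i in indices]
    if any(b <= a for a, b in zip(pts, pts[1:])):
        raise ValueError("zero-point indices must be strictly increasing")
    if not pts:
        return [], []
    merged: list[int] = []
    members: list[list[int]] = []
    cur = pts[0]
    cur_members = [pts[0]]
    for nxt in pts[1:]:
        if nxt - cur < min_gap:
            cur = -((cur + nxt) // -2)  # ceil of the arithmetic mean, exact in ints
            cur_members.append(nxt)
        else:
            merged.append(cur)
            members.append(cur_members)
            cur, cur_members = nxt, [nxt]
    merged.append(cur)
    members.append(cur_members)
    return merged, members


def select_windows(
    series: UniformSeries,
    N: int = DEFAULT_MAX_WINDOW,
    count: int = 3,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> ZeroPointSet:
    """Full selection pipeline: SAD curve -> jerk -> crossings -> merge -> first ``count``.

    Returns a :class:`ZeroPointSet` whose points are window lengths in
    samples.  Fewer than ``count`` crossings (e.g. for a constant signal) is
    allowed; the result is then flagged ``complete=False``.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    sad = compute_sad_curve(series, N)
    jerk = third_gradient(sad)
    crossing_idx = find_zero_crossings(jerk.values)
    crossing_windows = [int(sad.windows[i]) for i in crossing_idx]
    merged, members = merge_zero_points(crossing_windows, min_gap=merge_gap)
    return ZeroPointSet(
        points=tuple(merged[:count]),
        merged_from=tuple(tuple(m) for m in members[:count]),
        requested=count,
        complete=len(merged) >= count,
    )


def classic_flattening_window(
    sad: SADCurve,
    rel_tol: float = 0.01,
    span: int = 10,
):
    """Heuristic baseline: smallest window at which the SAD curve has flattened.

    Returns the smallest ``n`` such that the relative change of the SAD value
    over the next ``span`` windows is below ``rel_tol``, or ``None`` when no
    window qualifies ("did not flatten").  This is a documented stand-in for
    the informal eyeball-the-plateau window choice used with plain SAD
    curves; it is reported for comparison only and plays no part in the
    jerk-based selection.
    """
    if not (rel_tol > 0):
        raise ValueError("rel_tol must be positive")
    span = int(span)
    s = sad.sad_values
    if not (1 <= span < s.size):
        raise ValueError(f"span must be in [1, {s.size - 1}], got {span}")
    for i in range(s.size - span):
        base = abs(s[i])
        change = abs(s[i + span] - s[i])
        if base == 0.0:
            if change == 0.0:
                return int(sad.windows[i])
            continue
        if change / base < rel_tol:
            return int(sad.windows[i])
    return None
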