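"""Time-above-threshold metrics for heart-rate series.

Two cumulative measures commonly read off a heart-rate trace against a
threshold ``thr`` (e.g. the lower edge of a training zone):

* the **longest period** above the threshold — the maximum length of a
  maximal run of consecutive samples with ``HR >= thr``, measured as
  ``i_stop - i_start`` (fence-post convention: a run of k samples has
  length k-1 sample intervals);
* the **area above the threshold** — ``sum(HR[i] for HR[i] >= thr) - n*thr``
  with ``n`` the number of supra-threshold samples, converted to heart
  beats via ``bpm * seconds / 60``.

Because both metrics are sensitive to brief dips and spikes, they are
typically computed on a moving-average-filtered trace; ``threshold_report``
evaluates them for a list of candidate windows side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import moving_average
from .timeseries_io import UniformSeries

__all__ = [
    "Period",
    "ThresholdReport",
    "periods_above_threshold",
    "longest_period",
    "area_above_threshold",
    "total_area",
    "threshold_report",
]


@dataclass(frozen=True)
class Period:
    """A maximal run of consecutive samples at or above the threshold.

    Indices are 0-based and inclusive; ``length_samples = i_stop - i_start``
    so a single-sample excursion has length 0 but still contributes its one
    sample to the supra-threshold count.
    """

    i_start: int
    i_stop: int
    sample_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.i_stop < self.i_start:
            raise ValueError(f"i_stop {self.i_stop} < i_start {self.i_start}")

    @property
    def length_samples(self) -> int:
        return self.i_stop - self.i_start

    @property
    def n_samples(self) -> int:
        return self.i_stop - self.i_start + 1

    @property
    def length_s(self) -> float:
        return self.length_samples * self.sample_interval_s

    def as_row(self) -> tuple:
        start_s = self.i_start * self.sample_interval_s
        stop_s = self.i_stop * self.sample_interval_s
        return (start_s, stop_s, self.length_s)


@dataclass(frozen=True)
class ThresholdReport:
    """All threshold metrics of one (possibly filtered) series.

    ``filter_window`` is the moving-average window applied before measuring;
    0 means the raw signal.
    """

    thr: float
    filter_window: int
    periods: tuple
    l_max: float
    n_above: int
    area_above: float
    total_area: float

    def to_dict(self) -> dict:
        return {
            "thr": self.thr,
            "filter_window": self.filter_window,
            "n_periods": len(self.periods),
            "periods": [list(p.as_row()) for p in self.periods],
            "l_max_s": self.l_max,
            "n_above": self.n_above,
            "area_above_beats": self.area_above,
            "total_area_beats": self.total_area,
        }

    def periods_to_csv(self, path) -> None:
        rows = np.array([p.as_row() for p in self.periods]).reshape(-1, 3)
        np.savetxt(path, rows, delimiter=",", header="start_s,stop_s,length_s", comments="")


def _mask(series: UniformSeries, thr: float, inclusive: bool) -> np.ndarray:
    return series.values >= thr if inclusive else series.values > thr


def periods_above_threshold(
    series: UniformSeries, thr: float, inclusive: bool = True
) -> list[Period]:
    """Maximal runs of consecutive samples at or above ``thr``.

    The comparison is inclusive (``>=``) by default; pass ``inclusive=False``
    for a strict comparison as a sensitivity check.  Runs touching the series
    boundary open/close at the boundary index.
    """
    m = _mask(series, thr, inclusive)
    if not m.any():
        return []
    edges = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1)
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        stops = np.concatenate((stops, [m.size - 1]))
    dt = series.sample_interval_s
    return [Period(int(a), int(b), dt) for a, b in zip(starts, stops)]


def longest_period(series: UniformSeries, thr: float, inclusive: bool = True) -> float:
    """Longest period above the threshold, in seconds (0 when none exists)."""
    periods = periods_above_threshold(series, thr, inclusive)
    return max((p.length_s for p in periods), default=0.0)


def area_above_threshold(series: UniformSeries, thr: float, inclusive: bool = True) -> float:
    """Area between the trace and the threshold, in heart beats.

    ``(sum of supra-threshold values - n*thr)`` is in bpm·samples; one sample
    lasts ``sample_interval_s`` seconds and 1 bpm·s equals 1/60 beat.
    """
    m = _mask(series, thr, inclusive)
    n = int(m.sum())
    raw = float(series.values[m].sum()) - n * thr
    return raw * series.sample_interval_s / 60.0


def total_area(series: UniformSeries) -> float:
    """Total area under the trace, in heart beats (sum · interval / 60)."""
    return float(series.values.sum()) * series.sample_interval_s / 60.0


def _single_report(series: UniformSeries, thr: float, window: int, inclusive: bool) -> ThresholdReport:
    periods = periods_above_threshold(series, thr, inclusive)
    return ThresholdReport(
        thr=float(thr),
        filter_window=int(window),
        periods=tuple(periods),
        l_max=max((p.length_s for p in periods), default=0.0),
        n_above=sum(p.n_samples for p in periods),
        area_above=area_above_threshold(series, thr, inclusive),
        total_area=total_area(series),
    )


def threshold_report(
    series: UniformSeries,
    thr: float,
    windows,
    inclusive: bool = True,
) -> list[ThresholdReport]:
    """One :class:`ThresholdReport` per requested moving-average window.

    ``windows`` is a list of window lengths in samples; 0 (or 1) means the
    raw, unfiltered signal.
    """
    reports = []
    for w in windows:
        w = int(w)
        filtered = series if w in (0, 1) else moving_average(series, w)
        reports.append(_single_report(filtered, thr, w, inclusive))
    return reports
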