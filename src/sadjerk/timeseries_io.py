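"""Reading, cleaning and resampling of raw physiological recordings.

All downstream analysis operates on :class:`UniformSeries` — a uniformly
sampled, finite-valued, single-channel series.  Raw recordings (generic
two-column CSV, or the PAMAP2 protocol ``.dat`` dialect) are cleaned and
resampled to a uniform grid here, before any filtering or metric is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UniformSeries",
    "SeriesError",
    "GapError",
    "read_csv_series",
    "read_pamap2_dat",
    "clean_and_resample",
]

DEFAULT_MAX_GAP_S = 30.0


class SeriesError(ValueError):
    """Raised when an input recording cannot be turned into a uniform series."""


class GapError(SeriesError):
    """Raised when a gap in the recording exceeds the allowed maximum."""


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled numeric series.

    Parameters
    ----------
    values:
        Sample values (bpm for heart rate).  Must be finite and of length >= 2;
        cleaning happens *before* construction.
    sample_interval_s:
        Spacing between consecutive samples, in seconds.  Sample ``i`` covers
        the half-open interval ``[start + i*dt, start + (i+1)*dt)``.
    start_time_s:
        Time of the first sample (bin left edge), in seconds.
    label:
        Free-text units tag, e.g. ``"bpm"``.
    """

    values: np.ndarray
    sample_interval_s: float = 1.0
    start_time_s: float = 0.0
    label: str = "bpm"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise SeriesError(f"a series needs at least 2 samples, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise SeriesError("series values must all be finite; clean the input first")
        if not (self.sample_interval_s > 0):
            raise SeriesError(f"sample_interval_s must be positive, got {self.sample_interval_s}")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (bin left edges)."""
        return self.start_time_s + np.arange(len(self)) * self.sample_interval_s

    @property
    def duration_s(self) -> float:
        return len(self) * self.sample_interval_s

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        """Same grid and label, new values."""
        return UniformSeries(values, self.sample_interval_s, self.start_time_s, self.label)


def clean_and_resample(
    times,
    values,
    target_interval_s: float,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> UniformSeries:
    """Resample irregular samples onto a uniform grid.

    Samples are binned (bin mean) onto a grid of width ``target_interval_s``
    whose edges sit at integer multiples of the interval; empty bins are then
    filled by linear interpolation between the bracketing non-empty bins.
    A run of empty bins spanning more than ``max_gap_s`` raises
    :class:`GapError` rather than fabricating data.

    Already-uniform input at the target interval passes through unchanged.
    """
    if not (target_interval_s > 0):
        raise SeriesError("target_interval_s must be positive")
    if not (max_gap_s > 0):
        raise SeriesError("max_gap_s must be positive")
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise SeriesError("times and values must have equal length")
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    if t.size < 2:
        raise SeriesError("need at least 2 valid samples")
    if np.any(np.diff(t) <= 0):
        raise SeriesError("timestamps must be strictly increasing")

    # Grid-aligned bins: bin k covers [k*dt, (k+1)*dt).
    first_bin = math.floor(t[0] / target_interval_s)
    last_bin = math.floor(t[-1] / target_interval_s)
    n_bins = last_bin - first_bin + 1
    if n_bins < 2:
        raise SeriesError("input spans fewer than 2 output bins")

    idx = np.floor(t / target_interval_s).astype(np.int64) - first_bin
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    filled = counts > 0

    # Single-sample bins keep the sample value exactly (no division round-off).
    means = np.empty(n_bins)
    means[filled] = sums[filled] / counts[filled]
    one = counts == 1
    first_sample = np.cumsum(counts) - counts
    means[one] = v[first_sample[one]]

    if not filled.all():
        gap_edges = np.diff(filled.astype(np.int8))
        gap_starts = np.flatnonzero(gap_edges == -1) + 1
        gap_stops = np.flatnonzero(gap_edges == 1) + 1  # exclusive
        for a, b in zip(gap_starts, gap_stops):
            span = (b - a) * target_interval_s
            if span > max_gap_s:
                raise GapError(
                    f"gap of {span:g} s (bins {a}..{b - 1}) exceeds max_gap_s={max_gap_s:g}"
                )
        bins = np.arange(n_bins)
        means[~filled] = np.interp(bins[~filled], bins[filled], means[filled])

    return UniformSeries(
        means,
        sample_interval_s=float(target_interval_s),
        start_time_s=first_bin * target_interval_s,
    )


def read_csv_series(
    path,
    time_column: str = "time_s",
    value_column: str = "hr_bpm",
) -> UniformSeries:
    """Read a two-column CSV (time in seconds, value in bpm) into a uniform series.

    Rows with a missing value are dropped before resampling.  If the remaining
    samples are already uniformly spaced, their native interval is kept;
    otherwise the series is cleaned and resampled at 1 s.
    """
    frame = pd.read_csv(path)
    for col in (time_column, value_column):
        if col not in frame.columns:
            raise SeriesError(f"column {col!r} not found in {path} (has {list(frame.columns)})")
    t = frame[time_column].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise SeriesError("time column contains missing or non-finite entries")
    if np.any(np.diff(t) <= 0):
        raise SeriesError("timestamps must be strictly increasing")
    v = frame[value_column].to_numpy(dtype=float)
    keep = np.isfinite(v)
    t, v = t[keep], v[keep]
    if t.size < 2:
        raise SeriesError(f"fewer than 2 valid rows in {path}")
    dt = np.diff(t)
    if np.allclose(dt, dt[0], rtol=0.0, atol=1e-9):
        return UniformSeries(v, sample_interval_s=float(dt[0]), start_time_s=float(t[0]))
    return clean_and_resample(t, v, target_interval_s=1.0)


def read_pamap2_dat(path, max_gap_s: float = DEFAULT_MAX_GAP_S) -> UniformSeries:
    """Read heart rate from a PAMAP2 protocol ``.dat`` file.

    The format is whitespace-separated, no header: column 1 is the timestamp
    in seconds, column 3 the heart rate in bpm or the literal token ``NaN``
    (the HR channel is sampled far below the IMU rate, so most rows are
    missing).  Valid samples are binned per whole second (bin mean) and empty
    seconds are filled by linear interpolation via :func:`clean_and_resample`.
    """
    times: list[float] = []
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 3:
                raise SeriesError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                ts = float(fields[0])
                hr = float(fields[2])  # "NaN" parses to nan
            except ValueError as exc:
                raise SeriesError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            if math.isfinite(hr):
                times.append(ts)
                values.append(hr)
    if len(values) < 2:
        raise SeriesError(f"{path}: no usable heart-rate samples (need at least 2)")
    return clean_and_resample(times, values, target_interval_s=1.0, max_gap_s=max_gap_s)
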