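"""Length-preserving centered moving-average filtering.

This is the filter whose window length the rest of the package tunes.  The
window is centered on the current sample with left half-width
``floor((window-1)/2)`` and right half-width ``ceil((window-1)/2)`` (even
windows take the extra sample on the right), and is clipped to the available
samples at the series edges so that the output has the same length as the
input.  ``window=1`` is the identity.
"""

from __future__ import annotations

import numpy as np

from .timeseries_io import UniformSeries

__all__ = ["moving_average", "moving_average_values"]


def moving_average_values(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of a plain array; see :func:`moving_average`."""
    v = np.asarray(values, dtype=float)
    n = v.size
    window = int(window)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return v.copy()
    left = (window - 1) // 2
    right = window // 2
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n - 1)
    hi = np.clip(idx + right, 0, n - 1)
    csum = np.concatenate(([0.0], np.cumsum(v)))
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def moving_average(series: UniformSeries, window: int) -> UniformSeries:
    """Apply a centered moving-average filter of the given window length.

    Parameters
    ----------
    series:
        Input series.
    window:
        Window length in samples, ``1 <= window <= len(series)``.  At a 1 s
        sample interval this is also the window length in seconds.

    Returns
    -------
    UniformSeries
        Filtered series on the same grid (same length, interval and start).
    """
    return series.with_values(moving_average_values(series.values, window))
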