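"""Detrending, normalization and interval segmentation of reporter traces.

All downstream metrics operate on a common representation: a trace is a pair
``(times, values)`` of equal-length 1-d arrays with a uniform time grid in
hours.  Intervals are half-open ``[start, end)`` in hours from recording
start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["Interval", "detrend", "normalize", "segment"]


class InvalidWindowError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class BoundsError(ValueError):
    pass


@dataclass(frozen=True)
class Interval:
    """Half-open analysis interval [start, end), hours from recording start."""

    start: float
    end: float
    label: Literal["baseline", "treatment", "washout", "custom"] = "custom"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("interval end must exceed start")

    def mask(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.start) & (times < self.end)


def detrend(times: np.ndarray, values: np.ndarray, window: float = 24.0) -> np.ndarray:
    """Subtract a centred moving average of width ``window`` hours.

    Edges use shrinking (partial) windows so the output keeps the input
    length.  A window of one period nulls the fundamental's leakage into the
    trend estimate, so the default matches the nominal circadian period.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    dt = float(np.median(np.diff(times)))
    if window < 2 * dt:
        raise InvalidWindowError("window must be at least 2 samples wide")
    span = times[-1] - times[0]
    if window > span:
        raise InvalidWindowError("window exceeds record length")
    k = int(round(window / dt))
    if k % 2 == 0:
        # half-weight endpoints: the kernel spans exactly `window` hours and
        # annihilates any window-periodic component (e.g. the fundamental)
        kernel = np.ones(k + 1)
        kernel[0] = kernel[-1] = 0.5
    else:
        kernel = np.ones(k)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return values - num / den


def normalize(
    times: np.ndarray,
    values: np.ndarray,
    method: Literal["minmax", "zscore"] = "minmax",
    interval: Interval | None = None,
) -> np.ndarray:
    """Normalize a trace using statistics from ``interval`` (default: whole).

    ``minmax`` maps the interval minimum to 0 and maximum to 1; ``zscore``
    maps the interval to mean 0, sd 1.  The transform is applied to the whole
    trace, so values outside the interval may exceed [0, 1].
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interval is None:
        ref = values
    else:
        m = interval.mask(times)
        if not m.any():
            raise BoundsError("interval contains no samples")
        ref = values[m]
    if method == "minmax":
        lo, hi = float(np.min(ref)), float(np.max(ref))
        if hi == lo:
            raise DegenerateInputError("constant trace cannot be minmax-normalized")
        return (values - lo) / (hi - lo)
    if method == "zscore":
        mu, sd = float(np.mean(ref)), float(np.std(ref, ddof=1))
        if sd == 0:
            raise DegenerateInputError("constant trace cannot be z-scored")
        return (values - mu) / sd
    raise ValueError(f"unknown normalization method {method!r}")


def segment(
    times: np.ndarray, values: np.ndarray, intervals: list[Interval]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Slice a trace into views over non-overlapping half-open intervals."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    ordered = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError("intervals overlap")
    out = []
    for iv in intervals:
        if iv.start < times[0] - 1e-9 or iv.end > times[-1] + float(
            np.median(np.diff(times))
        ) + 1e-9:
            raise BoundsError(f"interval {iv} outside recording")
        m = iv.mask(times)
        out.append((times[m], values[m]))
    return out
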