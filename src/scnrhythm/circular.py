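"""Peak detection, circadian-time registration and circular statistics.

Event times (peaks, troughs) are registered to circadian time (CT) against
the slice's own TTFL reference rhythm: the reference channel's peak defines
CT12 (the start of circadian night), and elapsed time is rescaled by that
slice's fitted reference period, so one circadian hour is 1/24 of the
slice's own cycle.  Phases live on the 24 h circle; summaries use the mean
resultant vector, and uniformity is tested with the Rayleigh test or, when a
direction is hypothesized a priori, the V test (Rayleigh test against a
specified mean direction mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .preprocess import Interval
from .rhythm import _smooth, InsufficientDataError

__all__ = [
    "PhaseSample",
    "CircularStat",
    "WaveformAverage",
    "detect_peaks",
    "detect_troughs",
    "register_ct",
    "circular_mean",
    "circular_difference",
    "rayleigh_test",
    "v_test",
    "single_cycle_average",
]

HOURS_PER_CYCLE = 24.0


class RegistrationError(ValueError):
    pass


class EmptySampleError(ValueError):
    pass


class InsufficientSampleError(ValueError):
    pass


@dataclass
class PhaseSample:
    slice_id: str
    channel: str
    event: str  # "peak" or "trough"
    ct: float  # circadian time in [0, 24)

    def __post_init__(self) -> None:
        self.ct = float(self.ct) % HOURS_PER_CYCLE

    @property
    def angle(self) -> float:
        return 2.0 * np.pi * self.ct / HOURS_PER_CYCLE


@dataclass
class CircularStat:
    mean_ct: float
    r: float
    statistic: float
    p: float
    n: int
    mu: float | None = None
    unstable_mean: bool = False


@dataclass
class WaveformAverage:
    phase_grid: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)
    sem: np.ndarray = field(repr=False)
    n_cycles: int = 0


# --------------------------------------------------------------------------
# event detection


def detect_peaks(
    times: np.ndarray,
    values: np.ndarray,
    min_separation: float = 16.0,
    prominence_frac: float = 0.2,
) -> np.ndarray:
    """Peak times of the smoothed (median-3 then 2 h moving average) trace.

    Peaks must be separated by at least ``min_separation`` hours and have
    prominence at least ``prominence_frac`` of the trace's min-to-max range.
    Expects a detrended trace; may return an empty array.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(times) < 4:
        return np.array([])
    dt = float(np.median(np.diff(times)))
    sm = _smooth(values, dt)
    span = sm.max() - sm.min()
    if span == 0:
        return np.array([])
    distance = max(int(round(min_separation / dt)), 1)
    idx, _ = signal.find_peaks(sm, distance=distance, prominence=prominence_frac * span)
    return times[idx]


def detect_troughs(
    times: np.ndarray,
    values: np.ndarray,
    min_separation: float = 16.0,
    prominence_frac: float = 0.2,
) -> np.ndarray:
    """Trough times: peak detection on the negated trace."""
    return detect_peaks(times, -np.asarray(values, float), min_separation, prominence_frac)


# --------------------------------------------------------------------------
# CT registration


def register_ct(
    event_time: float,
    reference_peaks: np.ndarray,
    reference_period: float,
    slice_id: str = "",
    channel: str = "",
    event: str = "peak",
) -> PhaseSample:
    """Map an event time to circadian time against the reference rhythm.

    ct = (12 + 24 * (event_time - nearest reference peak) / reference_period)
    mod 24.  Every reference peak maps to exactly CT12; events before the
    first reference peak are registered against it by backward extrapolation.
    """
    peaks = np.atleast_1d(np.asarray(reference_peaks, float))
    if peaks.size == 0:
        raise RegistrationError("no reference peaks to register against")
    if not (16.0 <= reference_period <= 42.0):
        raise RegistrationError(
            f"reference period {reference_period} outside the circadian band"
        )
    nearest = peaks[int(np.argmin(np.abs(peaks - event_time)))]
    ct = (12.0 + HOURS_PER_CYCLE * (event_time - nearest) / reference_period) % 24.0
    return PhaseSample(slice_id=slice_id, channel=channel, event=event, ct=ct)


def _angles(phases) -> np.ndarray:
    out = []
    for p in phases:
        if isinstance(p, PhaseSample):
            out.append(p.angle)
        else:
            out.append(2.0 * np.pi * (float(p) % 24.0) / 24.0)
    return np.asarray(out)


def circular_mean(phases) -> tuple[float, float]:
    """Vector mean of unit phasors: (mean CT in [0, 24), resultant length R).

    When R is numerically zero (e.g. antipodal samples) the mean direction
    is undefined; the returned mean is then NaN.
    """
    ang = _angles(phases)
    if len(ang) == 0:
        raise EmptySampleError("no phases")
    z = np.exp(1j * ang).mean()
    r = float(np.abs(z))
    if r < 1e-12:
        return float("nan"), 0.0
    mean_ct = (np.angle(z) % (2.0 * np.pi)) * 24.0 / (2.0 * np.pi)
    return float(mean_ct), r


def circular_difference(ct_a: float, ct_b: float) -> float:
    """Signed circular difference a - b in hours, in (-12, 12]."""
    d = (float(ct_a) - float(ct_b)) % 24.0
    if d > 12.0:
        d -= 24.0
    return d


# --------------------------------------------------------------------------
# uniformity tests


def rayleigh_test(phases) -> CircularStat:
    """Rayleigh test of circular uniformity.

    Z = n R^2; p from the standard large-sample series approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Z^2)) - (1 + 2n)), clipped to [0, 1].
    """
    ang = _angles(phases)
    n = len(ang)
    if n < 3:
        raise InsufficientSampleError("Rayleigh test needs n >= 3")
    mean_ct, r = circular_mean(ang * 24.0 / (2 * np.pi))
    z = n * r * r
    # series approximation in the un-normalized resultant nR ((nR)^2 = nZ)
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - n * z)
    p = float(np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n)))
    p = min(max(p, 0.0), 1.0)
    return CircularStat(
        mean_ct=mean_ct,
        r=r,
        statistic=float(z),
        p=p,
        n=n,
        unstable_mean=r < 0.05,
    )


def v_test(phases, mu: float) -> CircularStat:
    """Rayleigh test against a specified mean direction mu (CT hours).

    V = R cos(mean angle - mu angle); u = V sqrt(2n); one-sided p from the
    standard normal upper tail of u with a one-term Edgeworth kurtosis
    correction.  Under uniformity u is a standardized sum of cos(theta_i)
    terms whose excess kurtosis is -3/2, so
    p = Phi_bar(u) + phi(u) * (3u - u^3) / (16 n),
    accurate to a few 1e-3 down to n = 4.
    """
    ang = _angles(phases)
    n = len(ang)
    if n < 3:
        raise InsufficientSampleError("V test needs n >= 3")
    if not (0.0 <= mu < 24.0):
        mu = float(mu) % 24.0
    mean_ct, r = circular_mean(ang * 24.0 / (2 * np.pi))
    mu_angle = 2.0 * np.pi * mu / 24.0
    mean_angle = 2.0 * np.pi * (mean_ct if np.isfinite(mean_ct) else 0.0) / 24.0
    v = r * np.cos(mean_angle - mu_angle)
    u = v * np.sqrt(2.0 * n)
    p = float(stats.norm.sf(u) + stats.norm.pdf(u) * (3 * u - u**3) / (16.0 * n))
    return CircularStat(
        mean_ct=mean_ct,
        r=r,
        statistic=float(u),
        p=min(max(p, 0.0), 1.0),
        n=n,
        mu=float(mu),
        unstable_mean=r < 0.05,
    )


# --------------------------------------------------------------------------
# single-cycle waveform average


def single_cycle_average(
    trace_sets,
    channel: str,
    reference_channel: str,
    phase_grid_step: float = 0.5,
    reference_period: float | None = None,
    detrend_window: float = 24.0,
) -> WaveformAverage:
    """Average minmax-normalized single cycles of ``channel`` on a CT grid.

    For every reference-channel peak-to-peak cycle, the target channel's
    samples are minmax-normalized within the cycle, their times mapped to CT
    (reference peak = CT12, rescaled by the slice's fitted reference period),
    linearly resampled onto a uniform CT grid, then averaged across cycles
    and slices.  SEM is across contributing cycles.
    """
    from .preprocess import detrend
    from .rhythm import fit_damped_cosine

    if not isinstance(trace_sets, (list, tuple)):
        trace_sets = [trace_sets]
    grid = np.arange(0.0, HOURS_PER_CYCLE, phase_grid_step)
    cycles = []
    for ts in trace_sets:
        t = ts.times
        ref_fit = fit_damped_cosine(t, ts.channels[reference_channel])
        ref = ts.channels[reference_channel] - (
            ref_fit.mesor + ref_fit.slope * (t - t[0])
        )
        # remove the target's fitted linear baseline rather than a moving
        # average: MA ripple (window != period) and residual trend both tilt
        # flat-topped waveforms and drag their apparent peak within the cycle
        tgt_fit = fit_damped_cosine(t, ts.channels[channel])
        tgt = ts.channels[channel] - (tgt_fit.mesor + tgt_fit.slope * (t - t[0]))
        period = ref_fit.period if reference_period is None else reference_period
        if ref_fit.converged:
            # fitted peak grid: exact cycle boundaries, free of the sample
            # quantization that tilts flat-topped waveforms after resampling
            n_cycles = max(int((t[-1] - ref_fit.acrophase) // ref_fit.period), 0)
            peaks = ref_fit.acrophase + ref_fit.period * np.arange(n_cycles + 1)
            peaks = peaks[(peaks >= t[0]) & (peaks <= t[-1])]
        else:
            peaks = detect_peaks(t, ref)
        if len(peaks) < 2:
            continue
        for a, b in zip(peaks[:-1], peaks[1:]):
            m = (t >= a) & (t <= b)
            if m.sum() < 4:
                continue
            seg_t, seg_v = t[m], tgt[m]
            lo, hi = seg_v.min(), seg_v.max()
            if hi == lo:
                continue
            seg_v = (seg_v - lo) / (hi - lo)
            # unwrapped CT across the cycle: 12 .. 12 + 24
            ct = 12.0 + HOURS_PER_CYCLE * (seg_t - a) / period
            on_grid = np.interp(
                np.where(grid < 12.0, grid + 24.0, grid), ct, seg_v,
                left=np.nan, right=np.nan,
            )
            cycles.append(on_grid)
    if not cycles:
        raise InsufficientDataError("no complete reference cycle found")
    arr = np.vstack(cycles)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        counts = np.sum(np.isfinite(arr), axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
        sem = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    return WaveformAverage(phase_grid=grid, mean=mean, sem=sem, n_cycles=len(cycles))


def register_acrophases(
    trace_sets,
    channel: str,
    reference_channel: str,
    detrend_window: float = 24.0,
) -> list[PhaseSample]:
    """One peak-phase sample per slice via fitted acrophases.

    For flat-peaked waveforms the sample-argmax peak time is a noisy,
    damping-biased phase estimator; the acrophase of the damped-cosine fit
    uses the whole record and is unbiased for any waveform symmetric about
    its peak.  Because period-estimation error accumulates when a fitted
    peak is projected away from the data that constrain it, the registered
    event is the fitted peak nearest the damping-weighted centre of the
    record, matched against the grid of reference fitted peak times
    (reference peak = CT12, rescaled by the slice's fitted reference
    period).
    """
    from .rhythm import fit_damped_cosine

    if not isinstance(trace_sets, (list, tuple)):
        trace_sets = [trace_sets]
    samples = []
    for ts in trace_sets:
        t = ts.times
        # fit on the raw traces: the model's linear baseline absorbs the
        # trend, and moving-average detrending distorts phase at the edges
        ref_fit = fit_damped_cosine(t, ts.channels[reference_channel])
        tgt_fit = fit_damped_cosine(t, ts.channels[channel])
        n_cycles = int((t[-1] - ref_fit.acrophase) // ref_fit.period) + 1
        ref_peaks = ref_fit.acrophase + ref_fit.period * np.arange(max(n_cycles, 1))
        w = np.exp(-2.0 * tgt_fit.damping * t)
        t_mid = float(np.sum(w * t) / np.sum(w))
        k = round((t_mid - tgt_fit.acrophase) / tgt_fit.period)
        event = tgt_fit.acrophase + k * tgt_fit.period
        samples.append(
            register_ct(
                event,
                ref_peaks,
                ref_fit.period,
                slice_id=ts.slice_id,
                channel=channel,
                event="peak",
            )
        )
    return samples


def phase_table(samples: list[PhaseSample]) -> pd.DataFrame:
    """Tidy phase table (slice, channel, event, ct, angle)."""
    return pd.DataFrame(
        [
            dict(
                slice_id=s.slice_id,
                channel=s.channel,
                event=s.event,
                ct=s.ct,
                angle=s.angle,
            )
            for s in samples
        ]
    )
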