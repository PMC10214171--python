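"""Per-trace rhythm metrics: period, amplitude, damping, RAE and RI.

Period and precision come from a nonlinear least-squares fit of a single
damped cosine with a linear baseline,

    y(t) = m + b*(t - t0) + A * exp(-lambda*(t - t0)) * cos(2*pi*(t - phi)/T),

the convention of FFT-NLLS-style circadian analysis restricted to the
fundamental.  The relative amplitude error (RAE) is the half-width of the
95% confidence interval of the fitted amplitude divided by the amplitude:
0 for a perfectly determined rhythm, > 1 when the amplitude is statistically
indistinguishable from zero.

Rhythm robustness is scored by the rhythmicity index (RI): the value of the
biased (length-normalized) sample autocorrelation at its first local maximum
at a circadian lag (>= 16 h by default).  A coherent multi-day rhythm gives
RI near (1 - T/record length); white noise gives RI near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .preprocess import Interval, detrend, DegenerateInputError

__all__ = [
    "RhythmFit",
    "RhythmicityIndex",
    "estimate_period_initial",
    "periodogram",
    "fit_damped_cosine",
    "rhythmicity_index",
    "minmax_amplitude",
    "peak_trough_series",
    "interval_change",
    "cohort_metrics",
    "with_baseline_deltas",
    "PERIOD_BAND",
]

PERIOD_BAND = (16.0, 42.0)
MAX_DAMPING = 0.1  # per hour


class InsufficientDataError(ValueError):
    pass


@dataclass
class RhythmFit:
    period: float
    acrophase: float  # time of first fitted peak within the interval (h)
    amplitude: float
    damping: float
    rae: float
    residual_sd: float
    converged: bool
    mesor: float = 0.0
    slope: float = 0.0


@dataclass
class RhythmicityIndex:
    ri: float
    lag_at_peak: float
    acf: np.ndarray = field(repr=False, default=None)
    no_peak: bool = False


# --------------------------------------------------------------------------
# periodogram


def periodogram(
    times: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float] = PERIOD_BAND,
    n_periods: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares (Lomb-Scargle) periodogram over a period band."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    periods = np.linspace(band[0], band[1], n_periods)
    freqs = 2.0 * np.pi / periods
    power = signal.lombscargle(times, values - values.mean(), freqs, normalize=True)
    return periods, power


def estimate_period_initial(
    times: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float] = PERIOD_BAND,
) -> float:
    """Period at the periodogram maximum, restricted to the search band."""
    times = np.asarray(times, float)
    span = times[-1] - times[0]
    if span < 2 * band[0]:
        raise InsufficientDataError(
            f"need at least {2 * band[0]:g} h of data, got {span:g} h"
        )
    periods, power = periodogram(times, values, band)
    return float(periods[int(np.argmax(power))])


def periodogram_low_power(
    times: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float] = PERIOD_BAND,
    n_shuffles: int = 200,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> bool:
    """True when the periodogram peak is unremarkable under a shuffle null."""
    rng = rng or np.random.default_rng(0)
    values = np.asarray(values, float)
    _, power = periodogram(times, values, band)
    observed = power.max()
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        _, p = periodogram(times, rng.permutation(values), band)
        null[i] = p.max()
    return observed <= np.quantile(null, 1.0 - alpha)


# --------------------------------------------------------------------------
# damped-cosine fit


def _damped_cosine(t, m, b, amp, lam, period, phi, t0):
    return m + b * (t - t0) + amp * np.exp(-lam * (t - t0)) * np.cos(
        2.0 * np.pi * (t - phi) / period
    )


def fit_damped_cosine(
    times: np.ndarray,
    values: np.ndarray,
    interval: Interval | None = None,
    period_init: float | None = None,
) -> RhythmFit:
    """Fit the damped cosine on an interval and report RAE.

    Bounded optimization (T in the circadian search band, damping in
    [0, 0.1] /h, amplitude >= 0) with three restarts at acrophase offsets
    {0, T/3, 2T/3}; the restart with the lowest residual wins.  RAE is the
    linearized 95% CI half-width of the amplitude over the amplitude.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interval is not None:
        m = interval.mask(times)
        times, values = times[m], values[m]
    if len(times) < 8:
        raise InsufficientDataError("too few samples for a damped-cosine fit")
    if np.std(values) == 0:
        raise DegenerateInputError("constant trace has no rhythm to fit")
    t0 = float(times[0])

    if period_init is None:
        try:
            period_init = estimate_period_initial(times, values)
        except InsufficientDataError:
            period_init = 24.0
    dtr = values - np.polyval(np.polyfit(times, values, 1), times)
    amp0 = max((dtr.max() - dtr.min()) / 2.0, 1e-12)
    m0 = float(values.mean())
    b0 = float(np.polyfit(times, values, 1)[0])

    lower = [-np.inf, -np.inf, 0.0, 0.0, PERIOD_BAND[0], -np.inf]
    upper = [np.inf, np.inf, np.inf, MAX_DAMPING, PERIOD_BAND[1], np.inf]

    best = None
    for frac in (0.0, 1.0 / 3.0, 2.0 / 3.0):
        p0 = [m0, b0, amp0, 0.01, period_init, t0 + frac * period_init]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    lambda t, m, b, a, lam, T, phi: _damped_cosine(
                        t, m, b, a, lam, T, phi, t0
                    ),
                    times,
                    values,
                    p0=p0,
                    bounds=(lower, upper),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = values - _damped_cosine(times, *popt, t0)
        ssr = float(resid @ resid)
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)

    if best is None:
        return RhythmFit(
            period=period_init,
            acrophase=t0,
            amplitude=amp0,
            damping=0.0,
            rae=np.inf,
            residual_sd=float(np.std(values)),
            converged=False,
            mesor=m0,
            slope=b0,
        )

    popt, pcov, ssr = best
    mesor, slope, amp, lam, period, phi = popt
    dof = max(len(times) - len(popt), 1)
    residual_sd = float(np.sqrt(ssr / dof))
    se_amp = float(np.sqrt(max(pcov[2, 2], 0.0))) if np.isfinite(pcov[2, 2]) else np.inf
    rae = 1.96 * se_amp / amp if amp > 0 else np.inf

    # first fitted peak at or after the interval start
    k = np.ceil((t0 - phi) / period)
    acrophase = float(phi + k * period)

    return RhythmFit(
        period=float(period),
        acrophase=acrophase,
        amplitude=float(amp),
        damping=float(lam),
        rae=float(rae),
        residual_sd=residual_sd,
        converged=True,
        mesor=float(mesor),
        slope=float(slope),
    )


# --------------------------------------------------------------------------
# rhythmicity index


def biased_acf(values: np.ndarray) -> np.ndarray:
    """Length-normalized sample autocorrelation (lag 0 .. n-1)."""
    x = np.asarray(values, float)
    x = x - x.mean()
    n = len(x)
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(n)
    full = np.correlate(x, x, mode="full")
    return full[n - 1 :] / denom


def rhythmicity_index(
    times: np.ndarray,
    values: np.ndarray,
    interval: Interval | None = None,
    min_lag: float = 16.0,
) -> RhythmicityIndex:
    """RI: biased ACF value at its first local maximum at lag >= min_lag.

    The search extends to half the record span; when no local maximum exists
    there, the maximum ACF value over the search range is returned with the
    ``no_peak`` flag set.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interval is not None:
        m = interval.mask(times)
        times, values = times[m], values[m]
    dt = float(np.median(np.diff(times)))
    span = times[-1] - times[0]
    if span < 2 * min_lag:
        raise InsufficientDataError("interval shorter than twice the minimum lag")
    acf = biased_acf(values)
    k_min = int(np.ceil(min_lag / dt))
    k_max = min(int(np.floor(span / 2.0 / dt)), len(acf) - 2)
    for k in range(max(k_min, 1), k_max + 1):
        if acf[k] > acf[k - 1] and acf[k] >= acf[k + 1]:
            return RhythmicityIndex(
                ri=float(acf[k]), lag_at_peak=k * dt, acf=acf, no_peak=False
            )
    seg = acf[k_min : k_max + 1]
    k_best = k_min + int(np.argmax(seg))
    return RhythmicityIndex(
        ri=float(acf[k_best]), lag_at_peak=k_best * dt, acf=acf, no_peak=True
    )


# --------------------------------------------------------------------------
# amplitude and per-cycle extrema


def minmax_amplitude(
    times: np.ndarray, values: np.ndarray, interval: Interval | None = None
) -> float:
    """Max minus min of the (already detrended) trace over the interval."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interval is not None:
        m = interval.mask(times)
        if not m.any():
            raise ValueError("empty interval")
        values = values[m]
    if len(values) == 0:
        raise ValueError("empty interval")
    return float(values.max() - values.min())


def _smooth(values: np.ndarray, dt: float, window_h: float = 2.0) -> np.ndarray:
    """3-sample median filter followed by a centred moving average."""
    med = signal.medfilt(np.asarray(values, float), kernel_size=3)
    n = max(int(round(window_h / dt)), 1)
    if n % 2 == 0:
        n += 1
    return (
        pd.Series(med).rolling(n, center=True, min_periods=1).mean().to_numpy()
    )


def _refine_extremum(
    times: np.ndarray, sm: np.ndarray, k: int, half_window: float, kind: str
) -> tuple[float, float]:
    """Quadratic refinement of an extremum: parabola vertex near sample k.

    Averages out residual sample noise without the selection bias of a raw
    argmin/argmax; falls back to the sample value when the local curvature
    has the wrong sign (e.g. a flat plateau).
    """
    m = (times >= times[k] - half_window) & (times <= times[k] + half_window)
    if m.sum() < 3:
        return float(times[k]), float(sm[k])
    a, b, c = np.polyfit(times[m] - times[k], sm[m], 2)
    ok = (a > 0) if kind == "trough" else (a < 0)
    if not ok:
        return float(times[k]), float(sm[k])
    x_v = -b / (2.0 * a)
    x_v = float(np.clip(x_v, -half_window, half_window))
    return float(times[k] + x_v), float(a * x_v * x_v + b * x_v + c)


def peak_trough_series(
    times: np.ndarray,
    values: np.ndarray,
    interval: Interval | None = None,
    period_hint: float = 24.0,
    prominence_frac: float = 0.2,
) -> pd.DataFrame:
    """Per-cycle peaks and troughs of the smoothed trace, on the raw scale.

    Cycles are delimited by successive detected peaks; each row holds the
    cycle's peak (time, value) and the trough (time, value) between that
    peak and the next.  The final peak, lacking a following trough, gets NaN
    trough fields.  When the record starts at least half a period before
    the first peak, the trough of that leading partial cycle is reported as
    cycle -1 with NaN peak fields (it carries real envelope information).
    Returns an empty frame when no cycles are detectable.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interval is not None:
        m = interval.mask(times)
        times, values = times[m], values[m]
    if len(times) < 4:
        return pd.DataFrame(
            columns=["cycle", "peak_time", "peak_value", "trough_time", "trough_value"]
        )
    dt = float(np.median(np.diff(times)))
    sm = _smooth(values, dt)
    # detrend only for detection; reported values stay on the raw scale
    try:
        det = detrend(times, sm, window=min(period_hint, times[-1] - times[0]))
    except Exception:
        det = sm - sm.mean()
    rng_amp = det.max() - det.min()
    if rng_amp == 0:
        return pd.DataFrame(
            columns=["cycle", "peak_time", "peak_value", "trough_time", "trough_value"]
        )
    distance = max(int(round(0.66 * period_hint / dt)), 1)
    idx, _ = signal.find_peaks(
        det, distance=distance, prominence=prominence_frac * rng_amp
    )
    refine_w = 0.1 * period_hint
    rows = []
    if len(idx) and times[idx[0]] - times[0] >= 0.5 * period_hint:
        k = int(np.argmin(sm[: idx[0] + 1]))
        tt, tv = _refine_extremum(times, sm, k, refine_w, "trough")
        rows.append(
            dict(
                cycle=-1,
                peak_time=np.nan,
                peak_value=np.nan,
                trough_time=tt,
                trough_value=tv,
            )
        )
    for c in range(len(idx)):
        i = idx[c]
        peak_time, peak_value = _refine_extremum(times, sm, i, refine_w, "peak")
        if c + 1 < len(idx):
            j = idx[c + 1]
            k = i + int(np.argmin(sm[i : j + 1]))
            trough_time, trough_value = _refine_extremum(times, sm, k, refine_w, "trough")
        else:
            trough_time, trough_value = np.nan, np.nan
        rows.append(
            dict(
                cycle=c,
                peak_time=float(peak_time),
                peak_value=float(peak_value),
                trough_time=float(trough_time),
                trough_value=float(trough_value),
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# baseline -> treatment changes


class MissingBaselineError(KeyError):
    pass


def interval_change(baseline: dict, treatment: dict) -> dict:
    """Delta record between baseline and treatment metric rows."""
    if baseline is None:
        raise MissingBaselineError("no baseline metrics for this slice/channel")
    out = {}
    for key in ("period", "rae", "ri"):
        if key in baseline and key in treatment:
            out[f"d_{key}"] = treatment[key] - baseline[key]
    if baseline.get("amplitude"):
        out["norm_amplitude"] = treatment.get("amplitude", np.nan) / baseline["amplitude"]
    else:
        out["norm_amplitude"] = np.nan
    return out


def _metric_row(times, values, interval, detrend_window, min_lag):
    det = detrend(times, values, window=detrend_window)
    # fit on the raw trace: the model's linear baseline absorbs the trend,
    # and moving-average detrending distorts phase/period near the edges
    fit = fit_damped_cosine(times, values, interval)
    ri = rhythmicity_index(times, det, interval, min_lag=min_lag)
    pts = peak_trough_series(times, values, interval, period_hint=fit.period)
    return dict(
        period=fit.period,
        rae=fit.rae,
        ri=ri.ri,
        amplitude=minmax_amplitude(times, det, interval),
        acrophase=fit.acrophase,
        damping=fit.damping,
        converged=fit.converged,
        peak_level=float(pts["peak_value"].mean()) if len(pts) else np.nan,
        trough_level=float(pts["trough_value"].mean()) if len(pts) else np.nan,
    )


def cohort_metrics(
    traces,
    intervals: list[Interval],
    channels: list[str] | None = None,
    detrend_window: float = 24.0,
    min_lag: float = 16.0,
) -> pd.DataFrame:
    """Tidy metrics table: one row per (slice, channel, interval label)."""
    rows = []
    for ts in traces:
        for name in channels or ts.channel_names():
            for iv in intervals:
                try:
                    row = _metric_row(
                        ts.times, ts.channels[name], iv, detrend_window, min_lag
                    )
                except (InsufficientDataError, DegenerateInputError):
                    continue
                row.update(slice_id=ts.slice_id, channel=name, interval=iv.label)
                rows.append(row)
    cols = [
        "slice_id",
        "channel",
        "interval",
        "period",
        "rae",
        "ri",
        "amplitude",
        "acrophase",
        "damping",
        "converged",
        "peak_level",
        "trough_level",
    ]
    return pd.DataFrame(rows, columns=cols)


def with_baseline_deltas(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append d_period/d_rae/d_ri/norm_amplitude columns vs. the baseline row."""
    metrics = metrics.copy()
    base = metrics[metrics["interval"] == "baseline"].set_index(
        ["slice_id", "channel"]
    )
    for col in ("d_period", "d_rae", "d_ri", "norm_amplitude"):
        metrics[col] = np.nan
    for i, row in metrics.iterrows():
        key = (row["slice_id"], row["channel"])
        if row["interval"] == "baseline" or key not in base.index:
            continue
        b = base.loc[key]
        delta = interval_change(
            dict(period=b["period"], rae=b["rae"], ri=b["ri"], amplitude=b["amplitude"]),
            dict(
                period=row["period"],
                rae=row["rae"],
                ri=row["ri"],
                amplitude=row["amplitude"],
            ),
        )
        for k, v in delta.items():
            metrics.at[i, k] = v
    return metrics
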