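"""Pharmacological treatment-effect quantification.

The key device is baseline-envelope extrapolation: straight lines fitted
through the per-cycle peak and trough levels of the baseline interval are
projected forward into the treatment interval, predicting where the peaks
and troughs *would* have fallen without treatment.  The ratio of observed to
predicted extrema then isolates trough-selective effects (e.g. a GABA-uptake
blocker elevating the circadian trough gives trough ratios > 1 with peak
ratios near 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Interval
from .rhythm import peak_trough_series

__all__ = [
    "EnvelopeModel",
    "RatioResult",
    "fit_envelopes",
    "predicted_actual_ratio",
    "prepost_ratio",
    "dose_response_table",
]


class InsufficientCyclesError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


@dataclass
class EnvelopeModel:
    """Baseline per-cycle peak and trough trend lines (raw-scale, au)."""

    peak_intercept: float
    peak_slope: float
    trough_intercept: float
    trough_slope: float
    n_baseline_cycles: int
    period_used: float
    last_peak_time: float
    last_trough_time: float

    def predict_peak(self, t: float) -> float:
        return self.peak_intercept + self.peak_slope * t

    def predict_trough(self, t: float) -> float:
        return self.trough_intercept + self.trough_slope * t


@dataclass
class RatioResult:
    peak_ratio: float
    trough_ratio: float
    per_cycle_peak: list = field(default_factory=list)
    per_cycle_trough: list = field(default_factory=list)
    skipped_cycles: int = 0


def fit_envelopes(
    baseline_events: pd.DataFrame, period_used: float | None = None
) -> EnvelopeModel:
    """OLS lines through baseline (time, value) peaks and troughs.

    ``baseline_events`` is the frame returned by
    :func:`scnrhythm.rhythm.peak_trough_series` over the baseline interval.
    """
    peaks = baseline_events.dropna(subset=["peak_time", "peak_value"])
    troughs = baseline_events.dropna(subset=["trough_time", "trough_value"])
    if len(peaks) < 2 or len(troughs) < 2:
        raise InsufficientCyclesError(
            "need >= 2 baseline peaks and >= 2 baseline troughs"
        )
    p_slope, p_int = np.polyfit(peaks["peak_time"], peaks["peak_value"], 1)
    t_slope, t_int = np.polyfit(troughs["trough_time"], troughs["trough_value"], 1)
    if period_used is None:
        period_used = float(np.mean(np.diff(peaks["peak_time"])))
    return EnvelopeModel(
        peak_intercept=float(p_int),
        peak_slope=float(p_slope),
        trough_intercept=float(t_int),
        trough_slope=float(t_slope),
        n_baseline_cycles=int(min(len(peaks), len(troughs))),
        period_used=float(period_used),
        last_peak_time=float(peaks["peak_time"].iloc[-1]),
        last_trough_time=float(troughs["trough_time"].iloc[-1]),
    )


def _actual_extremum(times, values, t_expect, half_window, kind) -> tuple[float, float] | None:
    from .rhythm import _refine_extremum

    m = (times >= t_expect - half_window) & (times <= t_expect + half_window)
    if not m.any():
        return None
    seg_t, seg_v = times[m], values[m]
    i = int(np.argmax(seg_v)) if kind == "peak" else int(np.argmin(seg_v))
    k = int(np.flatnonzero(m)[i])
    return _refine_extremum(times, values, k, 0.4 * half_window, kind)


def predicted_actual_ratio(
    times: np.ndarray,
    values: np.ndarray,
    model: EnvelopeModel,
    treatment_interval: Interval,
    match_frac: float = 0.25,
) -> RatioResult:
    """Mean actual/predicted peak and trough ratios over treatment cycles.

    Expected event times step forward from the last baseline event by the
    baseline period; the observed extremum is searched within +/-
    ``match_frac`` * period of each expected time (on the smoothed raw
    trace).  Cycles with no observable extremum are skipped and counted.
    Ratios are actual/predicted, so a treatment that elevates the trough
    yields trough ratios > 1.
    """
    from .rhythm import _smooth

    times = np.asarray(times, float)
    values = np.asarray(values, float)
    dt = float(np.median(np.diff(times)))
    sm = _smooth(values, dt)
    half_window = match_frac * model.period_used

    per_peak, per_trough = [], []
    skipped = 0
    for kind, t_last, predict in (
        ("peak", model.last_peak_time, model.predict_peak),
        ("trough", model.last_trough_time, model.predict_trough),
    ):
        k = 1
        while True:
            t_expect = t_last + k * model.period_used
            if t_expect >= treatment_interval.end:
                break
            k += 1
            if t_expect < treatment_interval.start:
                continue
            found = _actual_extremum(times, sm, t_expect, half_window, kind)
            if found is None:
                skipped += 1
                continue
            _, actual = found
            predicted = predict(t_expect)
            if predicted <= 0:
                skipped += 1
                continue
            (per_peak if kind == "peak" else per_trough).append(actual / predicted)
    if not per_peak and not per_trough:
        raise UndefinedRatioError("no observable extrema in the treatment interval")
    return RatioResult(
        peak_ratio=float(np.mean(per_peak)) if per_peak else float("nan"),
        trough_ratio=float(np.mean(per_trough)) if per_trough else float("nan"),
        per_cycle_peak=per_peak,
        per_cycle_trough=per_trough,
        skipped_cycles=skipped,
    )


def prepost_ratio(
    times: np.ndarray, values: np.ndarray, t_treat: float, window: float = 24.0
) -> float:
    """Mean over the first ``window`` h of treatment / mean over the last
    ``window`` h preceding it."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    pre = (times >= t_treat - window) & (times < t_treat)
    post = (times >= t_treat) & (times < t_treat + window)
    dt = float(np.median(np.diff(times)))
    if times[0] > t_treat - window + dt / 2 or times[-1] < t_treat + window - dt:
        raise ValueError("need a full window of data on each side of t_treat")
    return float(values[post].mean() / values[pre].mean())


def dose_response_table(
    metrics_with_deltas: pd.DataFrame, doses: dict[str, float]
) -> pd.DataFrame:
    """Per-dose mean +/- SEM of the baseline->treatment change metrics.

    ``doses`` maps slice_id -> dose (vehicle = 0).  Input is the treatment
    rows of :func:`scnrhythm.rhythm.with_baseline_deltas` output.  SEM is NaN
    for single-slice dose groups.
    """
    df = metrics_with_deltas[metrics_with_deltas["interval"] == "treatment"].copy()
    missing = set(df["slice_id"]) - set(doses)
    if missing:
        raise KeyError(f"missing dose labels for slices: {sorted(missing)}")
    df["dose"] = df["slice_id"].map(doses)
    value_cols = [
        c
        for c in (
            "d_period",
            "d_rae",
            "d_ri",
            "norm_amplitude",
            "peak_level",
            "trough_level",
        )
        if c in df.columns
    ]
    rows = []
    for (dose, channel), grp in df.groupby(["dose", "channel"]):
        n = len(grp)
        for col in value_cols:
            vals = grp[col].dropna()
            rows.append(
                dict(
                    dose=dose,
                    channel=channel,
                    metric=col,
                    mean=float(vals.mean()) if len(vals) else np.nan,
                    sem=float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else np.nan,
                    n=n,
                )
            )
    return pd.DataFrame(rows).sort_values(["channel", "metric", "dose"]).reset_index(
        drop=True
    )
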