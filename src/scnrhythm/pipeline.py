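"""Configuration and the end-to-end analysis pipeline.

The pipeline runs preprocess -> rhythm metrics -> phase registration ->
(treatment effects or initiation analysis, as configured) for every slice
and writes tidy CSV tables plus a JSON summary.  Every output directory
carries the configuration hash and seed so reruns are reproducible and
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular, initiation, rhythm, treatment
from .preprocess import Interval, detrend, normalize
from .simulate import TraceSet

log = logging.getLogger("scnrhythm")

__all__ = ["AnalysisConfig", "load_config", "run_pipeline", "ConfigurationError"]


class ConfigurationError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    detrend_window: float = 24.0
    normalization: str = "minmax"
    period_band: tuple[float, float] = (16.0, 42.0)
    min_separation: float = 16.0
    prominence_frac: float = 0.2
    min_lag: float = 16.0
    intervals: list[Interval] = field(default_factory=list)
    intervals_from_events: bool = True
    mu_peak: float = 19.7
    mu_trough: float = 8.2
    reference_channel: str = "PER2LUC"
    mode: str = "rhythm"  # rhythm | treatment | initiation
    envelope_match_frac: float = 0.25
    target_trough_offset: float = 8.5
    target_peak_offset: float = 5.0
    min_delay: float = 12.0
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.period_band
        if not (8.0 <= lo < hi <= 72.0):
            raise ConfigurationError("period band must lie within [8, 72] h")
        for w in (self.detrend_window, self.min_separation, self.min_lag):
            if w <= 0:
                raise ConfigurationError("all windows must be > 0")

    def hash(self) -> str:
        payload = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    intervals = [
        Interval(float(iv["start"]), float(iv["end"]), iv.get("label", "custom"))
        for iv in raw.pop("intervals", [])
    ]
    if "period_band" in raw:
        raw["period_band"] = tuple(raw["period_band"])
    return AnalysisConfig(intervals=intervals, **raw)


def _intervals_for(ts: TraceSet, config: AnalysisConfig) -> list[Interval]:
    if config.intervals:
        return config.intervals
    if config.intervals_from_events:
        t_treat = ts.event_time("treatment")
        if t_treat is not None:
            t_wash = ts.event_time("washout")
            end = ts.times[-1] + ts.dt
            ivs = [Interval(0.0, t_treat, "baseline")]
            if t_wash is not None:
                ivs += [
                    Interval(t_treat, t_wash, "treatment"),
                    Interval(t_wash, end, "washout"),
                ]
            else:
                ivs.append(Interval(t_treat, end, "treatment"))
            return ivs
        return [Interval(0.0, ts.times[-1] + ts.dt, "baseline")]
    raise ConfigurationError("no intervals configured and none derivable from events")


def _slice_phases(ts: TraceSet, config: AnalysisConfig) -> list[circular.PhaseSample]:
    if config.reference_channel not in ts.channels:
        return []  # no TTFL reference recorded: nothing to register against
    t = ts.times
    ref = detrend(t, ts.channels[config.reference_channel], config.detrend_window)
    ref_peaks = circular.detect_peaks(
        t, ref, config.min_separation, config.prominence_frac
    )
    if len(ref_peaks) == 0:
        return []
    ref_fit = rhythm.fit_damped_cosine(t, ref)
    samples = []
    for name in ts.channel_names():
        det = detrend(t, ts.channels[name], config.detrend_window)
        for kind, finder in (
            ("peak", circular.detect_peaks),
            ("trough", circular.detect_troughs),
        ):
            for ev in finder(t, det, config.min_separation, config.prominence_frac):
                samples.append(
                    circular.register_ct(
                        ev,
                        ref_peaks,
                        ref_fit.period,
                        slice_id=ts.slice_id,
                        channel=name,
                        event=kind,
                    )
                )
    return samples


def run_pipeline(
    config: AnalysisConfig, traces: list[TraceSet], outdir: str | Path | None = None
) -> dict:
    """Run the configured analysis over a cohort and write the results bundle.

    Per-slice failures are logged and skipped; raises only when every slice
    fails.  Returns the bundle (also written to ``outdir``).
    """
    if not traces:
        raise ConfigurationError("no input traces")
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_metrics, all_phases, ratio_rows, init_rows = [], [], [], []
    failures = 0
    for ts in traces:
        try:
            ivs = _intervals_for(ts, config)
            m = rhythm.cohort_metrics(
                [ts], ivs, detrend_window=config.detrend_window, min_lag=config.min_lag
            )
            all_metrics.append(m)
            all_phases.extend(_slice_phases(ts, config))

            if config.mode == "treatment":
                t_treat = ts.event_time("treatment")
                base = next(iv for iv in ivs if iv.label == "baseline")
                treat = next(iv for iv in ivs if iv.label == "treatment")
                for name in ts.channel_names():
                    events = rhythm.peak_trough_series(ts.times, ts.channels[name], base)
                    model = treatment.fit_envelopes(events)
                    rr = treatment.predicted_actual_ratio(
                        ts.times,
                        ts.channels[name],
                        model,
                        treat,
                        match_frac=config.envelope_match_frac,
                    )
                    ratio_rows.append(
                        dict(
                            slice_id=ts.slice_id,
                            channel=name,
                            peak_ratio=rr.peak_ratio,
                            trough_ratio=rr.trough_ratio,
                            skipped_cycles=rr.skipped_cycles,
                            prepost_ratio=treatment.prepost_ratio(
                                ts.times, ts.channels[name], t_treat
                            )
                            if t_treat is not None
                            else np.nan,
                        )
                    )
            elif config.mode == "initiation":
                init_rows.append(_initiation_row(ts, config))
        except Exception as exc:  # noqa: BLE001 - per-slice isolation
            failures += 1
            log.warning("slice %s failed: %s", ts.slice_id, exc)
    if failures == len(traces):
        raise RuntimeError("all slices failed")

    metrics = (
        rhythm.with_baseline_deltas(pd.concat(all_metrics, ignore_index=True))
        if all_metrics
        else pd.DataFrame()
    )
    phases = circular.phase_table(all_phases)

    bundle = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_slices": len(traces),
        "n_failures": failures,
    }
    metrics.to_csv(outdir / "metrics.csv", index=False)
    if len(phases):
        phases.to_csv(outdir / "phases.csv", index=False)
    if ratio_rows:
        pd.DataFrame(ratio_rows).to_csv(outdir / "ratios.csv", index=False)
    if init_rows:
        pd.DataFrame(init_rows).to_csv(outdir / "initiation.csv", index=False)
    summary = dict(bundle)
    if len(metrics):
        for col in ("period", "rae", "ri"):
            grp = metrics.groupby(["channel", "interval"])[col]
            summary[f"{col}_mean"] = {
                f"{ch}/{iv}": float(v) for (ch, iv), v in grp.mean().items()
            }
            summary[f"{col}_sem"] = {
                f"{ch}/{iv}": float(v) for (ch, iv), v in grp.sem().items()
            }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline done: config %s, %d slices", config.hash(), len(traces))
    bundle.update(metrics=metrics, phases=phases)
    if ratio_rows:
        bundle["ratios"] = pd.DataFrame(ratio_rows)
    if init_rows:
        bundle["initiation"] = pd.DataFrame(init_rows)
    return bundle


def _initiation_row(ts: TraceSet, config: AnalysisConfig) -> dict:
    t_treat = ts.event_time("treatment")
    if t_treat is None:
        raise ConfigurationError("initiation mode needs a 'treatment' event")
    t = ts.times
    ref_raw = ts.channels[config.reference_channel]
    ref = detrend(t, ref_raw, config.detrend_window)
    fp = initiation.detect_first_peak(
        t, ref, t_treat, min_delay=config.min_delay,
        min_separation=config.min_separation, prominence_frac=config.prominence_frac,
    )
    row = dict(slice_id=ts.slice_id, first_peak_time=np.nan, initiated=False)
    if fp is None:
        return row
    try:
        period = rhythm.fit_damped_cosine(
            t, ref, Interval(t_treat, t[-1] + ts.dt, "treatment")
        ).period
    except Exception:
        period = 24.0
    ref_tr, tgt_tr, tgt_pk = initiation.predicted_event_times(
        fp, period, config.target_trough_offset, config.target_peak_offset
    )
    row.update(
        first_peak_time=fp,
        initiated=True,
        period=period,
        predicted_ref_trough=ref_tr,
        predicted_target_trough=tgt_tr,
        predicted_target_peak=tgt_pk,
    )
    win = Interval(t_treat, t[-1] + ts.dt, "treatment")
    norm_ref = normalize(t, ref_raw, "minmax", win)
    try:
        row["rel_amplitude_ref"] = initiation.first_cycle_relative_amplitude(
            t, norm_ref, t_treat + fp, t_treat + ref_tr
        )
    except ValueError:
        pass
    targets = [c for c in ts.channel_names() if c != config.reference_channel]
    if targets:
        tgt = targets[0]
        norm_tgt = normalize(t, ts.channels[tgt], "minmax", win)
        try:
            row["rel_amplitude_target"] = initiation.first_cycle_relative_amplitude(
                t, norm_tgt, t_treat + tgt_pk, t_treat + tgt_tr
            )
        except ValueError:
            pass
    return row
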