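"""Synthetic multi-channel circadian recordings.

Emulates long-term organotypic SCN slice recordings: a bioluminescent TTFL
reference channel (PER2::LUC) plus fluorescent reporter channels (e.g.
extracellular GABA, neuronal calcium, extracellular VIP, membrane voltage).
Each channel is a damped, possibly asymmetric oscillation riding on a slow
baseline with additive Gaussian noise:

    y(t) = baseline + trend * t + A * exp(-lambda * t) * w((t - phi) mod T / T) + eps

where ``w`` is a mean-centred periodic waveform with its maximum at phase 0.
Pharmacological interventions rescale the oscillatory excursions (whole
amplitude, or peak/trough side selectively), shift the level, or change the
period, with an exponential approach to the treated regime and optional
washout.  Arrhythmic (clock-null) and de-novo initiation modes cover the
genetic experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ReporterSpec",
    "InterventionSpec",
    "CohortSpec",
    "TraceSet",
    "waveform_value",
    "generate_recording",
    "generate_cohort",
    "wildtype_cohort_spec",
    "write_cohort",
    "PERIOD_BAND",
]

#: admissible free-running period band (h); SCN networks sustain rhythms
#: across roughly this range under genetic/pharmacological manipulation.
PERIOD_BAND = (16.0, 42.0)


class InvalidParameterError(ValueError):
    """A spec field violates its admissible range."""


# --------------------------------------------------------------------------
# specs


@dataclass
class ReporterSpec:
    """One recorded channel of a slice.

    ``phase_offset`` is hours relative to the reference channel's peak; the
    reference channel has offset 0 and its peak defines circadian time 12.
    ``sharpness`` >= 1 controls waveform asymmetry: 1 is a plain cosine,
    larger values give a broad, flat peak and a sharp trough.
    """

    name: str
    modality: Literal["bioluminescence", "fluorescence"] = "bioluminescence"
    period: float = 24.0
    phase_offset: float = 0.0
    amplitude: float = 1.0
    damping_rate: float = 0.0
    waveform: Literal["cosine", "asymmetric"] = "cosine"
    sharpness: float = 1.0
    baseline_level: float = 0.0
    trend_slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.damping_rate < 0:
            raise InvalidParameterError("damping_rate must be >= 0")
        if self.sharpness < 1:
            raise InvalidParameterError("waveform sharpness must be >= 1")
        if self.amplitude > 0 and not (
            PERIOD_BAND[0] <= self.period <= PERIOD_BAND[1]
        ):
            raise InvalidParameterError(
                f"rhythmic period must lie in {PERIOD_BAND}, got {self.period}"
            )


@dataclass
class InterventionSpec:
    """Pharmacological treatment applied from ``start_time``.

    ``amplitude_scale`` multiplies the whole oscillatory term;
    ``peak_scale``/``trough_scale`` multiply only the positive/negative
    excursions about the running mean (so a trough_scale < 1 *elevates* the
    trough of the recorded signal).  The treated regime is approached
    exponentially with time constant ``transition_tau`` and reverted after
    ``washout_time`` with the same time constant.
    """

    start_time: float
    amplitude_scale: float = 1.0
    trough_scale: float = 1.0
    peak_scale: float = 1.0
    level_shift: float = 0.0
    new_period: float | None = None
    transition_tau: float = 0.0
    washout_time: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0:
            raise InvalidParameterError("amplitude_scale must be >= 0")
        if self.trough_scale <= 0 or self.peak_scale <= 0:
            raise InvalidParameterError("peak/trough scales must be > 0")
        if self.transition_tau < 0:
            raise InvalidParameterError("transition_tau must be >= 0")
        if self.washout_time is not None and self.washout_time <= self.start_time:
            raise InvalidParameterError("washout_time must exceed start_time")


@dataclass
class CohortSpec:
    """Declarative description of a cohort of synthetic slice recordings."""

    n_slices: int = 1
    duration: float = 120.0
    dt: float = 0.5
    reporters: list[ReporterSpec] = field(default_factory=list)
    interventions: list[InterventionSpec] = field(default_factory=list)
    mode: Literal["rhythmic", "arrhythmic", "initiation"] = "rhythmic"
    initiation_start: float = 0.0
    initiation_tau: float = 6.0
    inter_slice_period_sd: float = 0.0
    inter_slice_phase_sd: float = 0.0
    reference_peak_time: float = 26.0
    genotype: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise InvalidParameterError("n_slices must be >= 1")
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidParameterError("dt and duration must be > 0")
        for iv in self.interventions:
            if not (0 <= iv.start_time <= self.duration):
                raise InvalidParameterError(
                    "intervention start_time must lie within the recording"
                )


@dataclass
class TraceSet:
    """One slice's synchronized multi-channel recording."""

    slice_id: str
    times: np.ndarray
    channels: dict[str, np.ndarray]
    genotype: str = "WT"
    events: list[tuple[str, float]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise InvalidParameterError("times must be a 1-d grid of >= 2 points")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise InvalidParameterError("times must be uniformly spaced")
        self.times = t
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != t.shape:
                raise InvalidParameterError(
                    f"channel {name!r} length {v.shape} != times {t.shape}"
                )
            self.channels[name] = v

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def channel_names(self) -> list[str]:
        return list(self.channels)

    def event_time(self, label: str) -> float | None:
        for lab, t in self.events:
            if lab == label:
                return t
        return None


# --------------------------------------------------------------------------
# waveforms


def _asymmetric_cycle_mean(s: float) -> float:
    # E[(sin^2(theta/2))^s] over a uniform cycle = Gamma(s+1/2)/(sqrt(pi) Gamma(s+1))
    b = np.exp(gammaln(s + 0.5) - 0.5 * np.log(np.pi) - gammaln(s + 1.0))
    return 1.0 - 2.0 * b


def waveform_value(
    phase_fraction: float | np.ndarray,
    waveform: str = "cosine",
    sharpness: float = 1.0,
) -> float | np.ndarray:
    """Mean-centred periodic waveform, maximum at phase fraction 0.

    ``cosine`` is cos(2*pi*p).  ``asymmetric`` sharpens the trough of the
    cosine by raising its trough-side excursion to the power ``sharpness``
    (s = 1 recovers the cosine; larger s gives a broader, flatter peak and a
    sharper trough), then re-centres to zero cycle mean and rescales so the
    largest absolute excursion is 1.
    """
    if sharpness < 1:
        raise InvalidParameterError("waveform sharpness must be >= 1")
    p = np.asarray(phase_fraction, dtype=float)
    theta = 2.0 * np.pi * (p % 1.0)
    if waveform == "cosine":
        out = np.cos(theta)
    elif waveform == "asymmetric":
        if sharpness == 1.0:
            out = np.cos(theta)
        else:
            u = 0.5 * (1.0 + np.cos(theta))  # 1 at peak, 0 at trough
            g = 1.0 - 2.0 * (1.0 - u) ** sharpness
            m = _asymmetric_cycle_mean(sharpness)
            out = (g - m) / (1.0 + abs(m))
    else:
        raise InvalidParameterError(f"unknown waveform {waveform!r}")
    return float(out) if np.isscalar(phase_fraction) else out


# --------------------------------------------------------------------------
# single recording


def _transition_factor(t: np.ndarray, iv: InterventionSpec) -> np.ndarray:
    """0 before treatment, exponential approach to 1, exponential washout."""
    f = np.zeros_like(t)
    on = t >= iv.start_time
    if iv.transition_tau > 0:
        f[on] = 1.0 - np.exp(-(t[on] - iv.start_time) / iv.transition_tau)
    else:
        f[on] = 1.0
    if iv.washout_time is not None:
        off = t >= iv.washout_time
        if iv.transition_tau > 0:
            f_at_wash = 1.0 - np.exp(
                -(iv.washout_time - iv.start_time) / iv.transition_tau
            )
            f[off] = f_at_wash * np.exp(
                -(t[off] - iv.washout_time) / iv.transition_tau
            )
        else:
            f[off] = 0.0
    return f


def _phase_fraction(
    t: np.ndarray, period: float, phi: float, interventions: list[InterventionSpec]
) -> np.ndarray:
    """Phase fraction of the oscillation, allowing treatment period changes.

    Without a period-changing intervention this is exact arithmetic; with one,
    the instantaneous period blends between old and new with the intervention's
    transition factor and phase is accumulated by trapezoidal integration,
    keeping the cycle phase continuous through the treatment boundary.
    """
    period_ivs = [iv for iv in interventions if iv.new_period is not None]
    if not period_ivs:
        return ((t - phi) % period) / period
    t_eff = np.full_like(t, period, dtype=float)
    for iv in period_ivs:
        f = _transition_factor(t, iv)
        t_eff = t_eff + (iv.new_period - period) * f
    freq = 1.0 / t_eff
    theta = np.empty_like(t)
    theta[0] = (t[0] - phi) / period
    dtheta = 0.5 * (freq[1:] + freq[:-1]) * np.diff(t)
    theta[1:] = theta[0] + np.cumsum(dtheta)
    return theta % 1.0


def generate_recording(
    spec: CohortSpec,
    slice_seed: int,
    slice_id: str = "slice00",
    period_offset: float = 0.0,
    phase_offset: float = 0.0,
) -> TraceSet:
    """Simulate one slice of a cohort.

    ``period_offset``/``phase_offset`` are slice-level deviations (drawn by
    :func:`generate_cohort`) applied to every channel.  Identical
    ``(spec, slice_seed)`` yields bit-identical output.
    """
    if spec.dt <= 0 or spec.duration <= 0:
        raise InvalidParameterError("dt and duration must be > 0")
    n = int(round(spec.duration / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    rng = np.random.default_rng(slice_seed)

    channels: dict[str, np.ndarray] = {}
    for rep in spec.reporters:
        amp = 0.0 if spec.mode == "arrhythmic" else rep.amplitude
        period = rep.period + period_offset
        phi = spec.reference_peak_time + rep.phase_offset + phase_offset

        if amp > 0:
            pf = _phase_fraction(t, period, phi, spec.interventions)
            osc = (
                amp
                * np.exp(-rep.damping_rate * t)
                * waveform_value(pf, rep.waveform, rep.sharpness)
            )
        else:
            osc = np.zeros_like(t)

        if spec.mode == "initiation":
            gate = np.zeros_like(t)
            after = t >= spec.initiation_start
            if spec.initiation_tau > 0:
                gate[after] = 1.0 - np.exp(
                    -(t[after] - spec.initiation_start) / spec.initiation_tau
                )
            else:
                gate[after] = 1.0
            osc = osc * gate

        level = np.zeros_like(t)
        for iv in spec.interventions:
            f = _transition_factor(t, iv)
            osc = osc * (1.0 + (iv.amplitude_scale - 1.0) * f)
            pos = np.clip(osc, 0.0, None) * (1.0 + (iv.peak_scale - 1.0) * f)
            neg = np.clip(osc, None, 0.0) * (1.0 + (iv.trough_scale - 1.0) * f)
            osc = pos + neg
            level = level + iv.level_shift * f

        noise = rng.normal(0.0, rep.noise_sd, n) if rep.noise_sd > 0 else 0.0
        channels[rep.name] = (
            rep.baseline_level + rep.trend_slope * t + osc + level + noise
        )

    events: list[tuple[str, float]] = []
    if spec.mode == "initiation":
        events.append(("treatment", spec.initiation_start))
    for iv in spec.interventions:
        events.append(("treatment", iv.start_time))
        if iv.washout_time is not None:
            events.append(("washout", iv.washout_time))

    return TraceSet(
        slice_id=slice_id,
        times=t,
        channels=channels,
        genotype=spec.genotype,
        events=events,
        provenance={"seed": int(slice_seed), "cohort_seed": int(spec.seed)},
    )


def slice_seed_for(seed: int, index: int) -> int:
    """Deterministic per-slice seed from the cohort seed (fixed hashing)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_cohort(spec: CohortSpec) -> list[TraceSet]:
    """Simulate ``spec.n_slices`` slices with inter-slice period/phase spread."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(spec.seed)))
    period_offsets = rng.normal(0.0, spec.inter_slice_period_sd, spec.n_slices)
    phase_offsets = rng.normal(0.0, spec.inter_slice_phase_sd, spec.n_slices)
    if spec.inter_slice_period_sd == 0:
        period_offsets = np.zeros(spec.n_slices)
    if spec.inter_slice_phase_sd == 0:
        phase_offsets = np.zeros(spec.n_slices)
    traces = []
    for i in range(spec.n_slices):
        traces.append(
            generate_recording(
                spec,
                slice_seed=slice_seed_for(spec.seed, i),
                slice_id=f"slice{i:02d}",
                period_offset=float(period_offsets[i]),
                phase_offset=float(phase_offsets[i]),
            )
        )
    return traces


# --------------------------------------------------------------------------
# anchored defaults

#: default channel geometry of a wild-type multiplexed recording: the TTFL
#: reference (peak = CT12) with extracellular GABA peaking ~7.7 h later
#: (circadian night) and neuronal calcium ~6 h earlier (circadian day).
_WT_REFERENCE_PERIOD = 24.1
_WT_GABA_OFFSET = 7.7
_WT_CA_OFFSET = -6.0


def wildtype_reporters(
    noise_sd: float = 0.1,
    damping_rate: float = 0.018,
    amplitude: float = 1.0,
) -> list[ReporterSpec]:
    """Default reporter set: PER2::LUC reference, [GABA]e, neuronal [Ca2+]i."""
    return [
        ReporterSpec(
            name="PER2LUC",
            modality="bioluminescence",
            period=_WT_REFERENCE_PERIOD,
            phase_offset=0.0,
            amplitude=amplitude,
            damping_rate=damping_rate,
            waveform="cosine",
            baseline_level=2.0,
            trend_slope=-0.002,
            noise_sd=noise_sd,
        ),
        ReporterSpec(
            name="GABAe",
            modality="fluorescence",
            period=_WT_REFERENCE_PERIOD,
            phase_offset=_WT_GABA_OFFSET,
            amplitude=amplitude,
            damping_rate=damping_rate,
            waveform="asymmetric",
            sharpness=3.0,
            baseline_level=2.0,
            trend_slope=-0.002,
            noise_sd=noise_sd,
        ),
        ReporterSpec(
            name="Ca",
            modality="fluorescence",
            period=_WT_REFERENCE_PERIOD,
            phase_offset=_WT_CA_OFFSET,
            amplitude=amplitude,
            damping_rate=damping_rate,
            waveform="cosine",
            baseline_level=2.0,
            trend_slope=-0.002,
            noise_sd=noise_sd,
        ),
    ]


def wildtype_cohort_spec(
    n_slices: int = 8,
    duration: float = 120.0,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """Cohort of wild-type multiplexed recordings with realistic spread."""
    kwargs = dict(
        n_slices=n_slices,
        duration=duration,
        dt=0.5,
        reporters=wildtype_reporters(),
        inter_slice_period_sd=0.3,
        inter_slice_phase_sd=0.5,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


#: CRY1-driven initiated oscillations run long; the first initiated TTFL
#: peak follows treatment by roughly a cycle and a third.
_INITIATION_PERIOD = 26.95
_FIRST_PEAK_DELAY = 34.5


def initiation_cohort_spec(
    n_slices: int = 4,
    seed: int = 0,
    t_treat: float = 72.0,
    first_peak_delay: float = _FIRST_PEAK_DELAY,
    period: float = _INITIATION_PERIOD,
    duration: float = 216.0,
    noise_sd: float = 0.1,
    **overrides,
) -> CohortSpec:
    """Clock-null slices whose rhythm is switched on at ``t_treat``.

    The reference TTFL channel and an extracellular-GABA-like target channel
    are silent before treatment and grow in with the initiation gate; the
    reference phase is placed so the first full reference peak falls
    ``first_peak_delay`` hours after treatment.  The target keeps the
    wild-type circadian geometry (peak ~CT19.7), i.e. a real-hours offset of
    7.7 * period / 24 from the reference peak.
    """
    target_offset = 7.7 * period / 24.0
    reporters = [
        ReporterSpec(
            name="PER2LUC",
            modality="bioluminescence",
            period=period,
            phase_offset=0.0,
            amplitude=1.0,
            damping_rate=0.0,
            waveform="cosine",
            baseline_level=3.0,
            noise_sd=noise_sd,
        ),
        ReporterSpec(
            name="GABAe",
            modality="fluorescence",
            period=period,
            phase_offset=target_offset,
            amplitude=1.0,
            damping_rate=0.0,
            waveform="asymmetric",
            sharpness=3.0,
            baseline_level=3.0,
            noise_sd=noise_sd,
        ),
    ]
    kwargs = dict(
        n_slices=n_slices,
        duration=duration,
        dt=0.5,
        reporters=reporters,
        mode="initiation",
        initiation_start=t_treat,
        initiation_tau=8.0,
        reference_peak_time=t_treat + first_peak_delay,
        inter_slice_phase_sd=0.5,
        genotype="CRY1,2-null",
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


# --------------------------------------------------------------------------
# persistence (wide CSV + JSON sidecar)


def write_cohort(traces: list[TraceSet], outdir: str | Path) -> list[Path]:
    """Write each slice as a wide CSV plus a JSON metadata sidecar."""
    from . import io as _io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ts in traces:
        paths.append(_io.write_traces(ts, outdir / f"{ts.slice_id}.csv"))
    return paths


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)


def cohort_spec_to_json(spec: CohortSpec) -> str:
    return json.dumps(cohort_spec_to_dict(spec), indent=2)
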