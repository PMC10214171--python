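# Methods

## Signal model

Every recorded channel is treated as

y(t) = m + b·t + A·exp(−λt)·w(((t − φ) mod T)/T) + ε(t),  ε ~ N(0, σ²) iid,

with period T restricted to the circadian search band [16, 42] h (SCN
networks sustain rhythms across roughly that range under genetic and
pharmacological manipulation), damping λ ∈ [0, 0.1] h⁻¹, and a waveform
w that is mean-centred over one cycle with its maximum at phase 0.

Two waveform families are provided. `cosine` is cos(2πp). `asymmetric`
models reporters with a broad, flat peak and a sharp trough — the shape of
the extracellular-GABA signal — by power-sharpening the trough side of a
cosine: with u = (1 + cos 2πp)/2, g = 1 − 2(1 − u)^s for sharpness s ≥ 1
(s = 1 recovers the cosine exactly). The cycle mean of g is known in
closed form via E[sin^{2s}θ] = Γ(s+½)/(√π Γ(s+1)), so mean-centring is
exact. The centred waveform is rescaled by its maximum *absolute*
excursion, keeping |w| ≤ 1; rescaling by the peak value instead would push
the sharpened trough below −1, so the signature's [−1, 1] bound was given
priority over exact unit peak height. Consequence: for s > 1 the trough
excursion is larger than the peak excursion relative to baseline, which is
also what the real reporter geometry looks like.

## Synthetic recordings

The generator is first-class, tested code; its defaults are the study
conditions every simulation-based test runs under.

- Grid: dt = 0.5 h; baseline records 120 h (~5 d). Treatment runs use a
  144 h baseline + 60 h treatment window (see *Envelope extrapolation*).
- Wild-type cohort: reference period 24.1 h; [GABA]e offset +7.7 h
  (asymmetric, s = 3); [Ca2+]i offset −6.0 h; baseline level 3 (treatment
  scenarios) or 2 (wild-type multiplexed), slow drift −0.002 au/h.
- Noise and damping: σ = 10 % of amplitude, λ = 0.018 h⁻¹. These two were
  calibrated once, jointly, so that recovered metrics on clean simulations
  land in the regimes the field reports for healthy slices (reference
  channel RAE ≈ 0.06, RI ≈ 0.5–0.6). The asymmetric channel's RAE runs
  higher (≈ 0.12) because a single cosine cannot represent its waveform —
  an honest model-misfit cost, not extra noise.
- Interventions: applied from `start_time` with an exponential approach
  (time constant `transition_tau`; 0 = step), reverted after
  `washout_time` with the same constant. `amplitude_scale` multiplies the
  oscillatory term; `peak_scale`/`trough_scale` multiply only its
  positive/negative excursions (so trough_scale < 1 *elevates* the
  recorded trough); `new_period` blends the instantaneous period through
  the transition and accumulates phase by trapezoidal integration so the
  cycle phase is continuous at the treatment boundary.
- Arrhythmic mode zeroes all amplitudes (clock-null slices); initiation
  mode gates the oscillation with 1 − exp(−(t − onset)/τ_init), τ_init =
  6–8 h, emulating conditional clock rescue. The initiation cohort places
  the first full reference peak 34.5 h post-treatment with a 26.95 h
  period (long, as expected for CRY1-driven oscillations).
- Determinism: per-slice seeds are derived from the cohort seed with
  `numpy.random.SeedSequence(seed, spawn_key=(index,))`; identical
  spec + seed reproduces traces bitwise.

What the generator does *not* emulate: shot noise or any
intensity-dependent noise, nonlinear baseline drift, spatial structure,
missing samples, or cycle-to-cycle waveform variability. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of real imaging data.

## Preprocessing

Detrending subtracts a centred moving average. When the window is an even
number of samples the kernel takes half-weight endpoints, so it spans
exactly the window and annihilates any window-periodic component — a
one-period window therefore nulls the fundamental's leakage into the
trend. Edges use shrinking (normalized) windows to preserve length. The
edge bias extends half a window at each end; for that reason the
damped-cosine fit is applied to *raw* traces (its linear baseline absorbs
the trend), and detrended traces are used only where a zero-mean signal is
required: rhythmicity index, peak detection, min-max amplitude.
Normalization (minmax to [0, 1] or z-score) computes its statistics on a
chosen interval and applies the affine map to the whole trace. Intervals
are half-open [start, end) hours from recording start.

## Rhythm metrics

**Period initialization** uses a Lomb–Scargle periodogram restricted to
[16, 42] h; a permutation test (trace shuffling) flags low-power peaks.

**Damped-cosine fit**: bounded trust-region least squares with three
restarts at acrophase offsets {0, T/3, 2T/3}; lowest residual wins;
non-convergence returns the initializer values flagged `converged=False`.
RAE = 1.96·SE(A)/A from the linearized covariance. The acrophase is the
first fitted peak at or after the interval start.

**Rhythmicity index**: biased ACF (normalized by record length, so
|acf| ≤ 1 and values decay with lag), first local maximum at lag ≥ 16 h,
searched up to half the span; if no local maximum exists the maximum ACF
value on the range is returned with a `no_peak` flag. A pure cosine over
six cycles gives RI ≈ 1 − T/span ≈ 0.83 exactly as the estimator predicts.

**Per-cycle extrema**: the trace is smoothed (3-sample median filter, then
a 2 h centred moving average), peaks delimit cycles, troughs are the
minima between successive peaks, and both are refined by a local quadratic
fit (vertex of a parabola over ±0.1 T), which removes the selection bias
and most of the variance of a raw argmin/argmax. When the record starts at
least half a period before the first peak, the leading partial cycle's
trough is kept (cycle −1): it carries real envelope information. Values
are reported on the raw intensity scale, because treatment questions about
"the level of the trough" are about absolute levels.

## Phase registration and circular statistics

CT registration: ct = (12 + 24·(t_event − nearest reference peak)/T_ref)
mod 24, using each slice's own fitted reference period — one circadian
hour is 1/24 of that slice's cycle. Events before the first reference peak
are registered against it (backward extrapolation).

For cohort-level phase geometry the per-slice phase estimator is the
fitted acrophase, anchored at the damping-weighted centre of the record
and matched against the grid of reference fitted peaks. Two failure modes
of the naive estimators motivated this: (i) the sample argmax of a
flat-topped waveform under damping is biased *hours* early, because the
exponential envelope tilts the plateau; (ii) back-projecting a fitted peak
to the first cycle accumulates period-estimation error (≈ (T̂−T) per cycle
projected). The centre-anchored acrophase is unbiased for any waveform
symmetric about its peak and recovers configured offsets to ≲ 0.15 h under
the default noise. Sample-level peak/trough detection remains available
(`detect_peaks`/`register_ct`) and is what the pipeline's event tables
use.

Rayleigh test: Z = nR², p = exp(√(1 + 4n + 4(n² − nZ)) − (1 + 2n)) — the
standard series approximation written in the un-normalized resultant
(nR)² = nZ. Verified against 10⁵-draw Monte-Carlo nulls to |Δp| < 0.005
for n ≥ 5 over p ∈ [0.001, 0.2].

V test (specified mean direction μ): u = R·cos(θ̄ − μ)·√(2n). The plain
normal upper tail is off by up to ~0.006 at n = 5, so a one-term Edgeworth
kurtosis correction is applied: under uniformity u is a standardized sum
of cos θ terms with excess kurtosis −3/2, giving
p = Φ̄(u) + φ(u)·(3u − u³)/(16n), accurate to ~1–3·10⁻³ down to n = 4.
Both tests raise on n < 3; means with R < 0.05 are flagged unstable.

Single-cycle waveform averages: each reference peak-to-peak cycle of the
target channel is minmax-normalized, mapped samplewise to CT, linearly
resampled onto a 0.5 h CT grid (48 bins, matching dt), and averaged with
SEM across cycles and slices. Cycle boundaries use the fitted reference
peak grid, and the target's *fitted linear baseline* is removed rather
than a moving average: both choices exist because any residual tilt of
order 10⁻⁴ relocates the argmax of a plateau that is flat to < 10⁻⁴ over
±2 h. Even so, the peak *location* of a flat-topped waveform is only
determined to within its plateau; the trough, being sharp, is pinned
tightly. Cohort-level peak phasing should therefore be read from the
acrophase registration, not from the averaged waveform's argmax.

## Treatment quantification

Envelope extrapolation fits ordinary least-squares lines through baseline
(time, value) peaks and troughs on the raw scale and projects them to
expected event times (last baseline event + k·T). Observed extrema are
searched within ±0.25 T of each expected time (tolerant to
treatment-induced phase drift without double-counting cycles); missing
extrema skip the cycle with a flag. Ratios are **actual/predicted**, so an
elevated trough gives ratios > 1; per-cycle ratios are retained. The
default study conditions use a 144 h baseline (six cycles, including the
leading trough) and a 60 h treatment window: extrapolation error grows
linearly with distance, and these spans keep the vehicle ratio spread at
±4 % (sd) under 10 % noise. The exponential-envelope alternative is
deliberately not implemented; baseline guide lines are straight.

The pre/post ratio is the mean over the first 24 h of treatment divided by
the mean over the last 24 h before it — window means, not endpoint
differences, because endpoint differences of a suppressed-but-oscillating
trace are sign-unstable. Dose-response tables aggregate Δperiod, ΔRAE,
ΔRI, normalized amplitude and peak/trough levels per dose (vehicle =
dose 0) with SEM reported as missing for single-slice groups.

## Initiation analysis

The first initiated peak is the earliest detected peak ≥ 12 h after
treatment (excluding the acute, non-circadian treatment transient), and it
only counts if the post-treatment segment is genuinely rhythmic: its
autocorrelation must show a circadian peak with RI ≥ 0.25 (white noise
stays below 0.2 in ~95 % of realizations). Otherwise a no-initiation flag
(None) is returned — arrhythmic vehicle slices flag in > 90 % of seeds.

Predicted event times: reference trough = first peak − T/2; target trough
and peak by fixed offsets from the first peak. The default offsets (8.5 h
before, 5.0 h after) are reporting configuration — they encode a
wild-type-like phase relationship but are not derivable from the CT
geometry by simple period rescaling, so they are exposed as explicit
parameters; analyses that need geometric consistency with the generator
pass offsets computed from the configured CT phases (e.g. peak offset =
7.7·T/24). Reported times are rounded to 0.5 h; internal values keep full
precision. First-cycle relative amplitude is the difference of
minmax-normalized levels at the nominal peak and trough times (each a ±1 h
window mean): ≈ 1 for a coherent initiated cycle, centred on 0 for
arrhythmic traces.

## Numerical and design choices

- Time is hours from recording start everywhere; phases live on a 24 h
  circle; circular differences are taken in (−12, 12].
- The fit is single-component by design: every reported metric needs only
  the fundamental, and waveform shape is handled by the single-cycle
  average, not by harmonics.
- Degenerate inputs raise typed errors (constant traces, empty intervals,
  too-short records, missing baselines) rather than returning NaNs.
- Problem sizes in the test and acceptance runs (50-slice recovery
  cohorts, 20 seeds per condition, 500-seed nulls, 10⁵-draw Monte-Carlo
  nulls) were chosen so each check resolves its tolerance with comfortable
  sampling margin.
- The KS check of Rayleigh-p uniformity uses 2,000 samples, for which the
  95 % null quantile of the KS distance is 0.0304; values near 0.03 are
  therefore expected sampling noise, not miscalibration (measured median
  over seeds ≈ 0.019).

## Known limitations

- Linear interpolation is the only gap handling; no artifact/spike removal.
- Envelope lines are linear; strongly damped baselines would be better
  served by an exponential envelope, which is out of scope.
- The V test correction assumes a uniform null; it is not a two-sample
  test, and no Watson–Williams-style comparisons are provided.
- The TIFF front-end averages ROI pixels per frame (rectangles or
  polygons, optional background subtraction); it does not segment cells.
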