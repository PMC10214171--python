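"""Rhythm metric contracts: periodogram, damped-cosine fit, RI, amplitudes."""

import numpy as np
import pytest

from scnrhythm import (
    Interval,
    InterventionSpec,
    detrend,
    estimate_period_initial,
    fit_damped_cosine,
    generate_recording,
    interval_change,
    minmax_amplitude,
    peak_trough_series,
    rhythmicity_index,
)
from scnrhythm.rhythm import (
    InsufficientDataError,
    MissingBaselineError,
    biased_acf,
    periodogram_low_power,
)
from scnrhythm.preprocess import DegenerateInputError

from conftest import cosine_trace, single_channel_spec


class TestPeriodogram:
    @pytest.mark.parametrize("true_period", [24.0, 26.95])
    def test_noiseless_cosine(self, true_period):
        t, y = cosine_trace(period=true_period)
        assert estimate_period_initial(t, y) == pytest.approx(true_period, abs=0.2)

    def test_short_record_rejected(self):
        t, y = cosine_trace(duration=30.0)
        with pytest.raises(InsufficientDataError):
            estimate_period_initial(t, y)

    def test_white_noise_flagged_low_power(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 120.5, 0.5)
        y = rng.normal(0, 1, len(t))
        p = estimate_period_initial(t, y)
        assert 16.0 <= p <= 42.0
        assert periodogram_low_power(t, y, n_shuffles=200, rng=np.random.default_rng(3))

    def test_strong_rhythm_not_flagged(self):
        t, y = cosine_trace(noise_sd=0.2, seed=4)
        assert not periodogram_low_power(t, y, n_shuffles=100)


class TestDampedCosineFit:
    def test_exact_model_recovered(self):
        t, y = cosine_trace(period=24.5, baseline=2.0, phase=5.0)
        fit = fit_damped_cosine(t, y)
        assert fit.converged
        assert fit.period == pytest.approx(24.5, abs=0.01)
        assert fit.damping == pytest.approx(0.0, abs=1e-3)
        assert fit.rae < 0.01

    def test_acrophase_is_first_peak(self):
        t, y = cosine_trace(period=24.0, phase=5.0)
        fit = fit_damped_cosine(t, y)
        assert fit.acrophase == pytest.approx(5.0, abs=0.05)

    def test_noisy_cohort_period_recovery(self):
        errs = []
        for seed in range(8):
            spec = single_channel_spec(seed=seed, period=24.1, noise_sd=0.1)
            ts = generate_recording(spec, 100 + seed)
            fit = fit_damped_cosine(ts.times, ts.channels["x"])
            errs.append(abs(fit.period - 24.1))
        assert np.mean(errs) < 0.1

    def test_flat_trace_degenerate(self):
        t = np.arange(0, 120.5, 0.5)
        with pytest.raises(DegenerateInputError):
            fit_damped_cosine(t, np.full_like(t, 2.0))

    def test_amplitude_zero_noise_trace(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 120.5, 0.5)
        fit = fit_damped_cosine(t, rng.normal(5.0, 0.3, len(t)))
        assert (not fit.converged) or fit.rae > 1.0 or fit.amplitude < 0.1


class TestRhythmicityIndex:
    def test_pure_cosine_matches_bruteforce(self):
        t, y = cosine_trace(duration=144.0)
        res = rhythmicity_index(t, y)
        # independent O(n^2) biased ACF oracle
        x = y - y.mean()
        n = len(x)
        denom = sum(v * v for v in x)
        lag = int(round(res.lag_at_peak / 0.5))
        oracle = sum(x[i] * x[i + lag] for i in range(n - lag)) / denom
        assert res.ri == pytest.approx(oracle, abs=1e-12)
        assert res.ri == pytest.approx(1 - 24.0 / 144.0, abs=0.03)
        assert res.lag_at_peak == pytest.approx(24.0, abs=0.5)

    def test_white_noise_small(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(0, 120.5, 0.5)
            ri = rhythmicity_index(t, rng.normal(0, 1, len(t))).ri
            hits += abs(ri) < 0.2
        assert hits >= 95

    def test_sign_invariance(self):
        t, y = cosine_trace(noise_sd=0.1, seed=9)
        assert rhythmicity_index(t, y).ri == pytest.approx(
            rhythmicity_index(t, -y).ri
        )

    def test_short_interval_rejected(self):
        t, y = cosine_trace(duration=30.0)
        with pytest.raises(InsufficientDataError):
            rhythmicity_index(t, y)

    def test_biased_acf_bounded(self):
        rng = np.random.default_rng(1)
        acf = biased_acf(rng.normal(0, 1, 300))
        assert acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(acf) <= 1.0 + 1e-12)


class TestMinmaxAmplitude:
    def test_full_cycles(self):
        t, y = cosine_trace(amplitude=1.3)
        assert minmax_amplitude(t, y) == pytest.approx(2.6, rel=0.01)

    def test_constant_zero(self):
        t = np.arange(0, 48.5, 0.5)
        assert minmax_amplitude(t, np.zeros_like(t)) == 0.0

    def test_shift_and_reversal_invariance(self):
        t, y = cosine_trace(noise_sd=0.1, seed=3)
        a = minmax_amplitude(t, y)
        assert minmax_amplitude(t, y + 100.0) == pytest.approx(a)
        assert minmax_amplitude(t, y[::-1]) == pytest.approx(a)

    def test_treatment_suppression_ratio(self):
        spec = single_channel_spec(noise_sd=0.02)
        spec.duration = 240.0
        spec.interventions = [InterventionSpec(start_time=120.0, amplitude_scale=0.3)]
        ts = generate_recording(spec, 5)
        det = detrend(ts.times, ts.channels["x"], 24.0)
        base = minmax_amplitude(ts.times, det, Interval(12.0, 108.0))
        treat = minmax_amplitude(ts.times, det, Interval(132.0, 228.0))
        assert treat / base == pytest.approx(0.3, abs=0.05)


class TestPeakTroughSeries:
    def test_peak_levels_on_raw_scale(self):
        spec = single_channel_spec(noise_sd=0.0)
        ts = generate_recording(spec, 0)
        events = peak_trough_series(ts.times, ts.channels["x"])
        peaks = events.dropna(subset=["peak_value"])
        assert np.allclose(peaks["peak_value"], 4.0, rtol=0.01)

    def test_damped_decay_factor(self):
        lam = 0.01
        spec = single_channel_spec(noise_sd=0.0, damping_rate=lam)
        ts = generate_recording(spec, 0)
        ev = peak_trough_series(ts.times, ts.channels["x"]).dropna(subset=["peak_value"])
        osc = ev["peak_value"].to_numpy() - 3.0
        ratios = osc[1:] / osc[:-1]
        assert np.allclose(ratios, np.exp(-lam * 24.0), atol=0.02)

    def test_washout_recovery_monotone(self):
        spec = single_channel_spec(noise_sd=0.0)
        spec.duration = 360.0
        spec.interventions = [
            InterventionSpec(
                start_time=96.0,
                amplitude_scale=0.2,
                transition_tau=8.0,
                washout_time=192.0,
            )
        ]
        ts = generate_recording(spec, 0)
        ev = peak_trough_series(ts.times, ts.channels["x"], Interval(200.0, 360.5))
        peaks = ev.dropna(subset=["peak_value"])["peak_value"].to_numpy()
        assert len(peaks) >= 3
        assert np.all(np.diff(peaks) > 0)

    def test_flat_trace_empty(self):
        t = np.arange(0, 120.5, 0.5)
        ev = peak_trough_series(t, np.full_like(t, 2.0))
        assert len(ev) == 0


class TestIntervalChange:
    def test_identical_rows_zero_delta(self):
        row = dict(period=24.0, rae=0.06, ri=0.5, amplitude=2.0)
        d = interval_change(row, dict(row))
        assert d["d_period"] == 0.0
        assert d["d_rae"] == 0.0
        assert d["d_ri"] == 0.0
        assert d["norm_amplitude"] == 1.0

    def test_period_lengthening_recovered(self):
        spec = single_channel_spec(noise_sd=0.05, period=24.0)
        spec.duration = 264.0
        spec.interventions = [
            InterventionSpec(start_time=120.0, new_period=25.0, transition_tau=2.0)
        ]
        ts = generate_recording(spec, 8)
        fit_b = fit_damped_cosine(ts.times, ts.channels["x"], Interval(0.0, 120.0))
        fit_t = fit_damped_cosine(ts.times, ts.channels["x"], Interval(132.0, 264.5))
        d = interval_change(
            dict(period=fit_b.period, rae=fit_b.rae, ri=0.5, amplitude=1.0),
            dict(period=fit_t.period, rae=fit_t.rae, ri=0.5, amplitude=1.0),
        )
        assert d["d_period"] == pytest.approx(1.0, abs=0.15)

    def test_missing_baseline(self):
        with pytest.raises(MissingBaselineError):
            interval_change(None, dict(period=24.0))
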