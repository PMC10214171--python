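"""Circular statistics: CT registration, Rayleigh/V tests, waveform averages."""

import numpy as np
import pytest
from pingouin import circ_rayleigh, circ_vtest

from scnrhythm import (
    circular_difference,
    circular_mean,
    detect_peaks,
    detect_troughs,
    generate_cohort,
    rayleigh_test,
    register_ct,
    single_cycle_average,
    v_test,
)
from scnrhythm.circular import (
    InsufficientSampleError,
    RegistrationError,
    register_acrophases,
)
from scnrhythm.simulate import wildtype_cohort_spec

from conftest import cosine_trace


class TestDetectPeaks:
    def test_noiseless_cosine_spacing(self):
        t, y = cosine_trace(phase=12.0)
        peaks = detect_peaks(t, y)
        assert len(peaks) == 5
        assert np.allclose(np.diff(peaks), 24.0, atol=0.51)

    def test_min_separation_rejects_harmonic(self):
        t = np.arange(0, 120.5, 0.5)
        y = np.cos(2 * np.pi * t / 24.0) + 0.8 * np.cos(2 * np.pi * (t - 12.0) / 24.0)
        # two components 12 h apart; separation rule keeps one peak per cycle
        peaks = detect_peaks(t, y, min_separation=16.0)
        assert np.all(np.diff(peaks) >= 16.0)

    def test_prominence_threshold_monotone(self):
        # raising the prominence bar can only remove noise peaks
        t = np.arange(0, 120.5, 0.5)
        for seed in range(20):
            y = np.random.default_rng(seed).normal(0, 1, len(t))
            counts = [
                len(detect_peaks(t, y, prominence_frac=f)) for f in (0.2, 0.5, 0.9)
            ]
            assert counts[0] >= counts[1] >= counts[2]

    def test_troughs_are_negated_peaks(self):
        t, y = cosine_trace(phase=3.0)
        assert np.array_equal(detect_troughs(t, y), detect_peaks(t, -y))


class TestRegisterCT:
    def test_reference_peak_is_ct12(self):
        s = register_ct(50.0, np.array([26.0, 50.0, 74.0]), 24.0)
        assert s.ct == pytest.approx(12.0, abs=1e-12)

    def test_half_period_is_ct0(self):
        s = register_ct(26.0 + 12.0, np.array([26.0]), 24.0)
        assert s.ct == pytest.approx(0.0, abs=1e-12)

    def test_offset_7p7(self):
        s = register_ct(26.0 + 7.7, np.array([26.0]), 24.0)
        assert s.ct == pytest.approx(19.7, abs=1e-12)

    def test_rescaled_by_reference_period(self):
        s = register_ct(26.0 + 13.0, np.array([26.0]), 26.0)
        assert s.ct == pytest.approx(0.0, abs=1e-12)

    def test_no_reference_peaks(self):
        with pytest.raises(RegistrationError):
            register_ct(10.0, np.array([]), 24.0)


class TestCircularMean:
    def test_concentrated(self):
        m, r = circular_mean([19.7] * 5)
        assert m == pytest.approx(19.7)
        assert r == pytest.approx(1.0)

    def test_antipodal_degenerate(self):
        m, r = circular_mean([0.0, 12.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(m)

    def test_quarter_circle(self):
        m, r = circular_mean([0.0, 6.0])
        assert m == pytest.approx(3.0)
        assert r == pytest.approx(np.sqrt(2) / 2)

    def test_circular_difference_wraps(self):
        assert circular_difference(1.0, 23.0) == pytest.approx(2.0)
        assert circular_difference(23.0, 1.0) == pytest.approx(-2.0)


class TestRayleigh:
    def test_identical_phases(self):
        st = rayleigh_test([19.7] * 8)
        assert st.r == pytest.approx(1.0)
        assert st.p < 1e-4

    def test_uniform_grid(self):
        st = rayleigh_test(list(np.arange(0.0, 24.0, 3.0)))
        assert st.r == pytest.approx(0.0, abs=1e-12)
        assert st.p > 0.99

    def test_matches_pingouin(self):
        rng = np.random.default_rng(0)
        for n in (5, 8, 12):
            ct = rng.vonmises(0.0, 1.0, n) % (2 * np.pi) * 24 / (2 * np.pi)
            ours = rayleigh_test(list(ct))
            z_pg, p_pg = circ_rayleigh(2 * np.pi * np.asarray(ct) / 24.0)
            assert ours.statistic == pytest.approx(z_pg, rel=1e-9)
            assert ours.p == pytest.approx(p_pg, abs=0.01)

    def test_monte_carlo_oracle(self):
        # closed-form p within 0.005 of the resampling null (reduced draws)
        rng = np.random.default_rng(1)
        for n in (5, 8, 12):
            null_r = np.abs(
                np.exp(1j * rng.uniform(0, 2 * np.pi, (20000, n))).mean(axis=1)
            )
            for r_obs in (0.55, 0.7, 0.85):
                phases = _phases_with_r(r_obs, n)
                st = rayleigh_test(phases)
                if not (0.001 <= st.p <= 0.2):
                    continue
                p_mc = float((null_r >= st.r).mean())
                assert abs(st.p - p_mc) < 0.008  # 0.005 + MC noise at 20k draws

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            rayleigh_test([1.0, 2.0])

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(4)
        ct = list(rng.uniform(0, 24, 8))
        a = rayleigh_test(ct)
        b = rayleigh_test([(c + 5.3) % 24 for c in ct])
        assert b.r == pytest.approx(a.r)
        assert b.p == pytest.approx(a.p)
        assert circular_difference(b.mean_ct, a.mean_ct) == pytest.approx(5.3, abs=1e-9)


def _phases_with_r(r_target, n, spread_scale=1.0):
    """Deterministic phase set with approximately the requested R."""
    # evenly spread around 0 with width chosen to hit R
    from scipy.optimize import brentq

    def r_of(width):
        ang = np.linspace(-width, width, n)
        return abs(np.exp(1j * ang).mean()) - r_target

    w = brentq(r_of, 1e-6, np.pi)
    return list((np.linspace(-w, w, n) * 24 / (2 * np.pi)) % 24)


class TestVTest:
    def test_all_at_mu(self):
        from scipy import stats

        st = v_test([19.7] * 8, mu=19.7)
        u = np.sqrt(16.0)
        assert st.statistic == pytest.approx(u)
        assert st.p <= stats.norm.sf(u) + 1e-12
        assert st.p < 1e-4

    def test_anti_directional(self):
        st = v_test([7.7] * 8, mu=19.7)
        assert st.p > 0.5

    def test_matches_pingouin_statistic(self):
        rng = np.random.default_rng(2)
        ct = rng.vonmises(np.pi / 2, 2.0, 8) % (2 * np.pi) * 24 / (2 * np.pi)
        ours = v_test(list(ct), mu=6.0)
        _, p_pg = circ_vtest(2 * np.pi * np.asarray(ct) / 24.0, dir=np.pi / 2)
        assert ours.p == pytest.approx(p_pg, abs=0.01)

    def test_monte_carlo_oracle(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        for n in (4, 8):
            z = np.exp(1j * rng.uniform(0, 2 * np.pi, (20000, n))).mean(axis=1)
            u_null = np.real(z) * np.sqrt(2 * n)
            for u_obs in (1.5, 2.0, 2.5):
                p_ours = float(
                    stats.norm.sf(u_obs)
                    + stats.norm.pdf(u_obs) * (3 * u_obs - u_obs**3) / (16 * n)
                )
                p_mc = float((u_null >= u_obs).mean())
                assert abs(p_ours - p_mc) < 0.008


class TestSingleCycleAverage:
    def _cohort(self, noise_free=False, **kw):
        if noise_free:
            from scnrhythm.simulate import wildtype_reporters

            kw.setdefault(
                "reporters", wildtype_reporters(noise_sd=0.0, damping_rate=0.0)
            )
            kw.setdefault("inter_slice_phase_sd", 0.0)
            kw.setdefault("inter_slice_period_sd", 0.0)
        spec = wildtype_cohort_spec(n_slices=2, seed=21, **kw)
        return generate_cohort(spec)

    def test_reference_recovers_cosine(self):
        traces = self._cohort(noise_free=True)
        wa = single_cycle_average(traces, "PER2LUC", "PER2LUC")
        # analytic normalized cosine peaking at CT12
        expected = 0.5 * (1 + np.cos(2 * np.pi * (wa.phase_grid - 12.0) / 24.0))
        finite = np.isfinite(wa.mean)
        assert np.nanmax(np.abs(wa.mean[finite] - expected[finite])) < 0.02

    def test_antiphase_inversion_identity(self):
        traces = self._cohort()
        for ts in traces:
            ts.channels["neg"] = -ts.channels["PER2LUC"]
        wa_pos = single_cycle_average(traces, "PER2LUC", "PER2LUC")
        wa_neg = single_cycle_average(traces, "neg", "PER2LUC")
        finite = np.isfinite(wa_pos.mean) & np.isfinite(wa_neg.mean)
        assert np.nanmax(np.abs(wa_neg.mean[finite] - (1 - wa_pos.mean[finite]))) < 0.02

    def test_gaba_geometry(self):
        # broad flat night-time peak, sharp day-time trough: the trough is
        # pinned tightly; the peak can only be located to within the plateau
        traces = self._cohort(noise_free=True)
        wa = single_cycle_average(traces, "GABAe", "PER2LUC")
        finite = np.isfinite(wa.mean)
        grid = wa.phase_grid[finite]
        mean = wa.mean[finite]
        argmax_ct = grid[np.argmax(mean)]
        argmin_ct = grid[np.argmin(mean)]
        assert 17.0 <= argmax_ct <= 22.5  # within the circadian-night plateau
        assert 7.0 <= argmin_ct <= 9.0
        # the configured peak phase (CT ~19.7) sits within 1e-3 of the top
        at_config = mean[np.argmin(np.abs(grid - 19.7))]
        assert mean.max() - at_config < 1e-3


class TestRegisterAcrophases:
    def test_cohort_phase_geometry(self):
        traces = generate_cohort(wildtype_cohort_spec(n_slices=4, seed=5))
        for ch, expected in (("GABAe", 19.67), ("Ca", 6.03)):
            ph = register_acrophases(traces, ch, "PER2LUC")
            m, r = circular_mean(ph)
            assert abs(circular_difference(m, expected)) < 0.3
            assert r > 0.99
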