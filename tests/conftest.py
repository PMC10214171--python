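import numpy as np
import pytest

from scnrhythm import CohortSpec, ReporterSpec, generate_cohort


def cosine_trace(
    period=24.0,
    amplitude=1.0,
    baseline=0.0,
    phase=0.0,
    duration=120.0,
    dt=0.5,
    noise_sd=0.0,
    damping=0.0,
    trend=0.0,
    seed=0,
):
    """Plain damped-cosine trace on a uniform grid (direct construction)."""
    t = np.arange(0.0, duration + dt / 2, dt)
    y = baseline + trend * t + amplitude * np.exp(-damping * t) * np.cos(
        2 * np.pi * (t - phase) / period
    )
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return t, y


@pytest.fixture
def simple_cosine():
    return cosine_trace()


@pytest.fixture
def wt_cohort_small():
    """Two wild-type-like slices, cheap enough for unit tests."""
    from scnrhythm.simulate import wildtype_cohort_spec

    return generate_cohort(wildtype_cohort_spec(n_slices=2, seed=11))


def single_channel_spec(seed=0, **reporter_kwargs):
    kwargs = dict(name="x", period=24.0, amplitude=1.0, baseline_level=3.0)
    kwargs.update(reporter_kwargs)
    return CohortSpec(
        n_slices=1, duration=120.0, dt=0.5, reporters=[ReporterSpec(**kwargs)], seed=seed
    )
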