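import numpy as np
import pytest

from footvel import SimConfig, make_default_template


@pytest.fixture(scope="session")
def template():
    return make_default_template()


@pytest.fixture
def quiet_cfg():
    """Factory for noiseless, jitter-free configs (deterministic limit)."""

    def make(**kw):
        base = dict(
            n_subjects=1,
            noise_sd=0.0,
            stride_time_jitter=0.0,
            amplitude_jitter=0.0,
            subject_effect_sd=0.0,
            asymmetry_target=0.0,
            condition_effect=1.0,
            rng_seed=7,
        )
        base.update(kw)
        return SimConfig(**base)

    return make


@pytest.fixture(scope="session")
def sine_trial():
    """ImuTrial whose sagittal channel is a pure sine of period 0.77 s."""
    from footvel import ImuTrial

    fs, period, dur = 30.0, 0.77, 20.0
    t = np.arange(int(dur * fs)) / fs
    s = 20.0 * np.sin(2 * np.pi * t / period)
    return ImuTrial("sine", "left", "noFO", fs, t, s, 0.1 * s, 0.2 * s), period
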