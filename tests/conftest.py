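import numpy as np
import pytest

from optoarousal.synth import (
    ChannelModel,
    SleepSimConfig,
    SpontaneousModel,
    simulate_evoked_sweeps,
    simulate_sleep_recording,
)


@pytest.fixture(scope="session")
def evoked_ensemble():
    """100-sweep binomial-channel ensemble with known (N, i, b)."""
    model = ChannelModel(n_channels=100, unitary_current=1.0, open_prob_peak=0.6, peak_cv=0.1, baseline_noise_sd=2.0)
    sweeps, truth = simulate_evoked_sweeps(model, n_sweeps=100, fs=10_000.0, seed=11)
    return model, sweeps, truth


@pytest.fixture(scope="session")
def spont_model():
    return SpontaneousModel(rate=2.0, amplitude_mean=50.0, amplitude_cv=0.3, rise_tau=0.5, decay_tau=10.0)


@pytest.fixture(scope="session")
def short_sleep():
    """A 40-minute closed-loop session with sham and 10 Hz trials."""
    cfg = SleepSimConfig(duration_s=2400.0, stim_conditions=("sham", "10Hz"), seed=7)
    rec, truth = simulate_sleep_recording(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
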