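import numpy as np
import pytest

import trifle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free synthetic run: data is exactly maps @ mixing @ modes."""
    spec = trifle.SyntheticSpec(d=4, k=3, n_frames=3000, noise_sd=0.0,
                                seed=7, n_trials=8)
    run, truth = trifle.generate_run(spec)
    return run, truth


@pytest.fixture(scope="session")
def noisy_modulated_run():
    """Noisy run with a planted slow sinusoidal modulation of weight (0, 0)."""
    spec = trifle.SyntheticSpec(
        d=4, k=3, n_frames=3000, noise_sd=0.5, seed=7, n_trials=8,
        modulation=(trifle.Modulation(network=0, mode=0, waveform="sinusoid",
                                      amplitude=0.5, frequency=0.005),))
    run, truth = trifle.generate_run(spec)
    return run, truth


@pytest.fixture()
def small_events():
    return trifle.generate_events(6, seed=1, run_length=400.0)
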