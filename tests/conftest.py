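import numpy as np
import pytest

from attnerp import SimulationConfig, preprocess_recording, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_p1():
    """Noise-free, blink-free single-subject oddball recording + epochs."""
    cfg = SimulationConfig(
        paradigm="P1", sampling_rate=125.0, n_trials=4,
        noise_sigma=0.0, eog_rate=0.0, seed=5,
    )
    rec, events = simulate_recording(cfg)
    eps, log, _ = preprocess_recording(rec, events, run_ica=False)
    return cfg, rec, events, eps


@pytest.fixture(scope="session")
def noisy_p1():
    """Realistic single-subject oddball recording, preprocessed with ICA."""
    cfg = SimulationConfig(paradigm="P1", sampling_rate=125.0, n_trials=8, seed=7)
    rec, events = simulate_recording(cfg)
    eps, log, report = preprocess_recording(rec, events)
    return cfg, rec, events, eps, report
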