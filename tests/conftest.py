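import numpy as np
import pytest

from tpear import detect_events_diao, detect_events_tpear
from tpear.simulate import GaitSimConfig, simulate_trial


@pytest.fixture(scope="session")
def clean_sim():
    """One noiseless 20-stride trial with ground truth."""
    cfg = GaitSimConfig(n_cycles=20, noise_sd=0.0, gyro_noise_sd=0.0, seed=7)
    trial, truth = simulate_trial(cfg)
    return cfg, trial, truth


@pytest.fixture(scope="session")
def clean_diao_events(clean_sim):
    _, trial, _ = clean_sim
    return detect_events_diao(trial)


@pytest.fixture(scope="session")
def clean_tpear_events(clean_sim):
    _, trial, _ = clean_sim
    return detect_events_tpear(trial)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
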