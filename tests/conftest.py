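import logging

import numpy as np
import pytest

from toolkin import SimConfig, Trajectory, simulate_trial

logging.getLogger("toolkin").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free, artefact-free simulation settings for oracle comparisons."""
    return SimConfig(
        noise_sd=0.0,
        dropout_prob=0.0,
        dwell_jitter_speed=0.0,
        submovement_prob=0.0,
        seed=7,
    )


@pytest.fixture
def clean_trial(clean_config):
    return simulate_trial(clean_config, {"site": "aSMG", "stim_type": "sham"}, trial_key=1)


def straight_line_trajectory(speed=0.3, duration=2.0, rate=100.0, direction=(1.0, 0.0, 0.0)):
    """Constant-velocity trajectory along a fixed direction."""
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    p = speed * t[:, None] * d[None, :]
    return Trajectory(t=t, p=p, sample_rate=rate, trial_id="line")


def stationary_trajectory(duration=2.0, rate=100.0, point=(0.1, 0.2, 0.3)):
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    p = np.tile(np.asarray(point, dtype=float), (n, 1))
    return Trajectory(t=t, p=p, sample_rate=rate, trial_id="still")
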