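import numpy as np
import pytest

from hffm.synthetic import GaitWaveformConfig, generate_trial, make_template_foot


@pytest.fixture(scope="session")
def template_r():
    return make_template_foot("R", 1.0)


@pytest.fixture(scope="session")
def template_l():
    return make_template_foot("L", 1.0)


@pytest.fixture(scope="session")
def noiseless_trial(template_r):
    """Two-cycle noiseless trial with ground truth and exact events."""
    cfg = GaitWaveformConfig(noise_sd_mm=0.0, n_cycles=2, seed=0)
    traj, truth, events = generate_trial(template_r, cfg)
    return traj, truth, events


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


def random_rotation(rng):
    """Uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
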