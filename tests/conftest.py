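import numpy as np
import pytest

import gaitmos as g


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled trial for fast unit tests (12 steps/foot, 5 s warm-up)."""
    return g.GaitSimConfig(
        n_participants=2, steps_per_foot_per_speed=12, warmup_s=5.0, seed=7
    )


@pytest.fixture(scope="session")
def trial(small_config):
    return g.generate_gait_trial(small_config, participant=0, speed_kmh=3.0)


@pytest.fixture(scope="session")
def step_samples(trial):
    return g.step_samples_from_trial(trial)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
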