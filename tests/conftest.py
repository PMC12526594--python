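import numpy as np
import pytest

from tsfnet import (SimulationConfig, build_samples, make_montage,
                    preprocess_study, simulate_subject)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_montage():
    return make_montage(n_eeg=8, n_fnirs=8, seed=3)


def tiny_sim_config(**overrides):
    """A fast two-session study: full tensor geometry, few trials."""
    base = dict(
        n_sessions=2, trials_per_session=4, rest_period_s=10.0,
        inter_trial_interval_s=32.0, seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_study(small_montage):
    return simulate_subject(tiny_sim_config(), small_montage)


@pytest.fixture(scope="session")
def tiny_samples(tiny_study):
    return build_samples(preprocess_study(tiny_study))
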