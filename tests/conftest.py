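import numpy as np
import pytest

from broilergait import (
    CleaningConfig,
    GaitParams,
    PoseConfig,
    noiseless,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_params():
    return GaitParams()


@pytest.fixture(scope="session")
def noiseless_params():
    return noiseless()


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_params):
    """Three noiseless walkers at d33, reused across tests."""
    return simulate_cohort(noiseless_params, n_good=2, n_suboptimal=1,
                           ages=(33,), seed=101, n_repeat=0)


@pytest.fixture(scope="session")
def noisy_cohort(default_params):
    """Small default-noise cohort at d33."""
    return simulate_cohort(default_params, n_good=5, n_suboptimal=4,
                           ages=(33,), seed=202, n_repeat=0)


@pytest.fixture()
def clean_none():
    return CleaningConfig(smoothing="none")


@pytest.fixture()
def pose_config():
    return PoseConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
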