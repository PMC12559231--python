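import numpy as np
import pytest

from visres import model as rmodel
from visres import synthetic as syn


@pytest.fixture(scope="session")
def channel_params():
    return rmodel.default_channel_params()


@pytest.fixture(scope="session")
def pop_models():
    return syn.default_population_models()


@pytest.fixture(scope="session")
def small_study():
    """A 4-observer synthetic study, reused across read-only tests."""
    return syn.generate_study_dataset(n_observers=4, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
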