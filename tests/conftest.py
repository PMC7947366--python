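import numpy as np
import pytest

from t2nomo import PhantomConfig


@pytest.fixture(scope="session")
def echo_times():
    return 9.9 * np.arange(1, 9)


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 8 bilateral patients on a small grid."""
    return PhantomConfig(n_patients=8, grid_shape=(32, 32, 8), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
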