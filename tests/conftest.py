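import numpy as np
import pytest

from eegclean import TimeSeries, default_scenario, linear_scenario


@pytest.fixture(scope="session")
def nonlinear_scenario():
    """Default nonlinear blink scenario, one fixed seed."""
    return default_scenario(seed=0)


@pytest.fixture(scope="session")
def linear_blink_scenario():
    """Identity-pathway scenario (0.8 direct + 0.3 delayed tap)."""
    return linear_scenario(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_series(rng):
    return TimeSeries(rng.standard_normal(512), 256.0, "noise")
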