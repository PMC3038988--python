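import numpy as np
import pytest
from hypothesis import settings

import pgptransfer as pt

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid():
    return pt.ActivityGrid()


@pytest.fixture(scope="session")
def day0(grid):
    """Default day-0 co-culture template (50:50 sensitive:resistant)."""
    return pt.day0_coculture_template(grid=grid)


@pytest.fixture(scope="session")
def linear_params():
    """The co-culture transfer estimates with thresholds on the linear axis."""
    return pt.TransferParams(
        tau=0.4, sigma=0.2, delta_min=10.0 ** 1.4, delta_max=10.0 ** 1.9,
        threshold_space="linear",
    )


@pytest.fixture(scope="session")
def log_params():
    """The co-culture transfer estimates in the simulation (log10) space."""
    return pt.default_transfer_params()


@pytest.fixture(scope="session")
def growth_model():
    return pt.GrowthModel()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
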