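import numpy as np
import pytest

from p53pool.calibration import CalibrationConfig, pool_targets
from p53pool.ode import simulate
from p53pool.parameters import REFERENCE_PARAMETERS
from p53pool.pool import ModelPool
from p53pool.synthetic import DEFAULT_MODIFIERS


@pytest.fixture(scope="session")
def ref_params():
    return REFERENCE_PARAMETERS


@pytest.fixture(scope="session")
def ref_simulation():
    """Reference simulation of the undamaged-to-damaged transition, 24 h."""
    return simulate(REFERENCE_PARAMETERS, t_span=(0.0, 24.0))


@pytest.fixture(scope="session")
def two_pool():
    """A two-subpopulation pool with distinct, pulsatile members."""
    return ModelPool(shared=REFERENCE_PARAMETERS,
                     modifiers=DEFAULT_MODIFIERS[[1, 2]].copy(),
                     weights=np.array([0.5, 0.5]))


@pytest.fixture(scope="session")
def two_pool_targets(two_pool):
    """Noiseless peak-based means generated from the two-member pool."""
    return pool_targets(two_pool, CalibrationConfig())
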