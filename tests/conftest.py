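import numpy as np
import pytest

from rolerev import (
    InitialCondition,
    ModelParameters,
    build_grid,
    initialize_state,
)


@pytest.fixture
def params():
    """Reference parameter set (sharp maturity transition)."""
    return ModelParameters()


@pytest.fixture
def coarse_grid(params):
    """A coarse lifespan-capped grid (fast tests)."""
    return build_grid(0.05, params.tau_star, params.L)


@pytest.fixture
def default_state(params, coarse_grid):
    return initialize_state(InitialCondition.default(params), coarse_grid, params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
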