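import numpy as np
import pytest

from racwaves import (
    ModelParameters,
    integrate,
    make_initial_state,
    solve_homogeneous_steady_state,
)


@pytest.fixture(scope="session")
def baseline_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline_steady(baseline_params):
    return solve_homogeneous_steady_state(baseline_params)


@pytest.fixture(scope="session")
def baseline_run(baseline_params):
    """Long traveling-wave run at default parameters, shared by the
    simulation, analysis and acceptance tests (transient ends ~4000 s)."""
    init = make_initial_state(baseline_params, snr_db=30.0, seed=5)
    return integrate(baseline_params, init, 8000.0, cadence=2.0)


@pytest.fixture(scope="session")
def baseline_transient():
    return 4000.0
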