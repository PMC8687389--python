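import numpy as np
import pytest

from aemglucose import model
from aemglucose.design import (
    REFERENCE_K,
    REFERENCE_L,
    SynthesisOptions,
    synthesize_controller,
    synthesize_observer,
)
from aemglucose.simulate import run_scenario_1


@pytest.fixture(scope="session")
def nominal():
    return model.NOMINAL_PATIENT


@pytest.fixture(scope="session")
def mats():
    return model.build_matrices(model.NOMINAL_PATIENT)


@pytest.fixture(scope="session")
def default_bounds():
    return model.default_bounds()


#: Narrow near-equilibrium operating box over which the scalar
#: Lipschitz channel of the synthesis LMIs is feasible (the full
#: physiological box provably is not; see the design docstrings).
NARROW_BOX = model.StateBox(x1d=(-3.0, 3.0), x2d=(0.0, 5e-4), x3d=(-5.0, 5.0), d=(0.0, 0.5))

#: Small parametric variation for uncertain-case tests.
NARROW_RANGES = model.ParamRanges(
    c2=(0.0147, 0.0153), c3=(1.96e-6, 2.04e-6), c4=(0.196, 0.204), c5=(0.049, 0.051)
)

SMALL_OPTS = SynthesisOptions(
    alpha_grid=(0.01, 0.05), eps_grid=(1e-3, 1e-2, 0.1, 1.0)
)


@pytest.fixture(scope="session")
def narrow_bounds():
    return model.default_bounds(model.NOMINAL_PATIENT, NARROW_RANGES, NARROW_BOX)


@pytest.fixture(scope="session")
def narrow_certain_bounds():
    """Narrow box, no parametric uncertainty, no exogenous disturbance."""
    b = model.default_bounds(model.NOMINAL_PATIENT, NARROW_RANGES, NARROW_BOX)
    return b.replace(delta=0.0, D_plus=0.0, ranges=None)


@pytest.fixture(scope="session")
def observer_design_narrow(mats, narrow_bounds):
    return synthesize_observer(mats, narrow_bounds, SMALL_OPTS)


@pytest.fixture(scope="session")
def controller_design_narrow(mats, narrow_bounds):
    return synthesize_controller(mats, narrow_bounds, SMALL_OPTS)


@pytest.fixture(scope="session")
def reference_gains():
    return REFERENCE_K, REFERENCE_L


@pytest.fixture(scope="session")
def scenario1_traj():
    return run_scenario_1()
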