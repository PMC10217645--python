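import numpy as np
import pytest

from persistext.model_core import ModelParams
from persistext.wkb import solve_instanton


@pytest.fixture(scope="session")
def std_params():
    """Production-style parameters: B=1.1, K=500, alpha=beta=0.02."""
    return ModelParams(B_ref=1.1, K=500, alpha=0.02, beta=0.02)


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale parameters for oracle-checked simulation tests."""
    return ModelParams(B_ref=1.3, K=25, alpha=0.05, beta=0.05)


@pytest.fixture(scope="session")
def std_instanton(std_params):
    """Converged instanton at the production parameters (reused widely)."""
    return solve_instanton(std_params, B=1.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230505)
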