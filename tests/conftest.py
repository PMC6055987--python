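import numpy as np
import pytest

from caraflgi.gittins import build_gittins_table
from caraflgi.io import fixture_worked_example


@pytest.fixture(scope="session")
def table_small():
    """Depth-64 index table at d=0.99: covers every unit test's states."""
    return build_gittins_table(max_depth=64, discount=0.99, tolerance=1e-3)


@pytest.fixture(scope="session")
def table_full():
    """Depth-452 table at d=0.99: deep enough for N=450 trials with lookahead."""
    return build_gittins_table(max_depth=452, discount=0.99, tolerance=1e-4)


@pytest.fixture(scope="session")
def worked_state():
    """Posterior state [(2,1); (1,1); (1,1); (2,1)] after the first block."""
    return fixture_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
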