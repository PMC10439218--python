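import warnings

import pytest

from aquamap.grid import (
    CATEGORICAL, NUMERICAL, FeatureLayer, FeatureStack, GridSpec, build_cell_table,
)
from aquamap.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default desk-scale world: 60x60, 5 numeric + 2 categorical layers,
    3 access types."""
    return generate_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def default_table(default_world):
    return default_world.cell_table()


@pytest.fixture(scope="session")
def small_world():
    return generate_world(WorldConfig(n_rows=30, n_cols=30, seed=5))


@pytest.fixture()
def tiny_table():
    """Four-cell table: two urban cells (pop 1, 3), two rural (pop 10, 0)."""
    grid = GridSpec(2, 2)
    stack = FeatureStack(grid, [FeatureLayer("f", NUMERICAL, [0.0, 1.0, 2.0, 3.0])])
    pop = FeatureLayer("population", NUMERICAL, [1.0, 3.0, 10.0, 0.0])
    strata = FeatureLayer("stratum", CATEGORICAL, [1, 1, 0, 0])
    return build_cell_table(stack, pop, strata)


@pytest.fixture(autouse=True)
def _quiet_convergence():
    """MLP runs in the suite use small iteration caps on purpose."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="MLP did not converge")
        warnings.filterwarnings("ignore", message="Stochastic Optimizer")
        yield
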