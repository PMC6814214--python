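import numpy as np
import pytest

from proptab import CountTable2x2, make_table
from proptab.synthetic import random_tables


@pytest.fixture(scope="session")
def fig_table() -> CountTable2x2:
    """The worked example table (a, b, c, d) = (10, 30, 30, 20)."""
    return make_table(10, 30, 30, 20)


@pytest.fixture(scope="session")
def uniform_table() -> CountTable2x2:
    return make_table(5, 5, 5, 5)


@pytest.fixture(scope="session")
def table_pool():
    """1000 seeded random tables with positive margins, shared across
    property tests."""
    return random_tables(1000, max_total=300, seed=20240901)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(77)
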