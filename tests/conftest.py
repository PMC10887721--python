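import numpy as np
import pytest

from dispci import StrataTable, adjusted_rates


@pytest.fixture
def rng():
    return np.random.default_rng(20240208)


@pytest.fixture
def two_group_table():
    """2 groups x 2 ages, equal person-years: Y = (0.02, 0.04)."""
    return StrataTable(events=[[2, 2], [4, 4]],
                       person_years=[[100.0, 100.0], [100.0, 100.0]],
                       weights=[0.5, 0.5])


@pytest.fixture
def three_group_adjusted():
    """A moderately dense 3x4 table with distinct group rates."""
    table = StrataTable(
        events=[[12, 20, 35, 18], [20, 30, 52, 25], [30, 45, 80, 41]],
        person_years=[[4000.0, 3800.0, 3500.0, 2500.0],
                      [3000.0, 2900.0, 2700.0, 1900.0],
                      [5000.0, 4800.0, 4500.0, 3200.0]],
        weights=[0.4, 0.3, 0.2, 0.1],
    )
    return table, adjusted_rates(table)


def random_config(rng, J=None, positive=True):
    """Random (rates, p, z) with shares from a Dirichlet draw."""
    J = J or int(rng.integers(2, 6))
    p = rng.dirichlet(np.ones(J))
    z = np.cumsum(p) - p / 2.0
    low = 0.2 if positive else 0.0
    rates = rng.uniform(low, 3.0, J)
    return rates, p, z
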