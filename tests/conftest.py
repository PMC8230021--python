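import numpy as np
import pytest

from bonje import DecisionTable, NeighborhoodDecisionSystem, toy_table


@pytest.fixture(scope="session")
def toy():
    return toy_table()


@pytest.fixture(scope="session")
def toy_nds(toy):
    return NeighborhoodDecisionSystem(toy, delta=0.3, p=2.0)


def random_system(rng, n_max=8, m_max=4, delta=None, n_classes=2):
    """Small random neighborhood decision system for property tests."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    values = rng.uniform(0, 1, (n, m)).round(3)
    labels = tuple(f"c{v}" for v in rng.integers(0, n_classes, n))
    if delta is None:
        delta = float(rng.choice(np.arange(1, 10) / 10))
    table = DecisionTable(values, labels)
    return NeighborhoodDecisionSystem(table, delta=delta, p=2.0)
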