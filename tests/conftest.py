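import numpy as np
import pytest

import alarmforest as af
from alarmforest.examples import EXAMPLE_INBAG, EXAMPLE_TREE_PROBS, example_trace


@pytest.fixture
def trace_3x4():
    """The hand-checkable 3-observation, 4-tree trace."""
    return example_trace()


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated two-class data (n=100) for forest round-trips."""
    return af.generate_dataset(
        af.SyntheticSpec(n_pos=40, n_neg=60, p=5, n_informative=3,
                         delta=2.0, seed=11, name="separable"))


@pytest.fixture(scope="session")
def fitted(separable_dataset):
    """One fitted forest plus its trace, shared across tests."""
    forest = af.fit_forest(separable_dataset, af.ForestConfig(n_trees=40, seed=7))
    trace = af.extract_trace(forest, separable_dataset)
    return separable_dataset, forest, trace


def random_trace(rng, n=None, m=None):
    """A random fractional trace for property tests."""
    n = n or int(rng.integers(2, 12))
    m = m or int(rng.integers(1, 9))
    probs = rng.random((n, m))
    inbag = rng.integers(0, 2, size=(n, m))
    return af.EnsembleTrace(tree_probs=probs, inbag=inbag)
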