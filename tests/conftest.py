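import numpy as np
import pytest


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_two_class():
    """Small well-separated two-class problem: feature 0 informative."""
    local = np.random.default_rng(555)
    n_per = 30
    X = local.standard_normal((2 * n_per, 5))
    X[n_per:, 0] += 4.0
    y = np.concatenate([-np.ones(n_per, dtype=int), np.ones(n_per, dtype=int)])
    return X, y


@pytest.fixture
def imbalanced_labels():
    """40 majority (-1) and 10 minority (+1) labels."""
    return np.concatenate([-np.ones(40, dtype=int), np.ones(10, dtype=int)])
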