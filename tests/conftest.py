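import numpy as np
import pytest

from chainlump import (
    Partition,
    stationary_distribution,
    validate_stochastic,
    worked_example_matrix,
)


@pytest.fixture(scope="session")
def worked_chain():
    """The 4-state worked example at p=0.3, q=0.2, with its stationary
    distribution and closed 2-block partition."""
    T = worked_example_matrix(0.3, 0.2)
    pi = stationary_distribution(T)
    good = Partition.from_blocks([("a", "c"), ("b", "d")])
    return T, pi, good


@pytest.fixture
def make_random_chain():
    """Factory for dense random chains with sorted letter labels."""

    def _make(n, seed):
        rng = np.random.default_rng(seed)
        labels = tuple(f"x{i:02d}" for i in range(n))
        return validate_stochastic(labels, rng.dirichlet(np.ones(n), size=n))

    return _make
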