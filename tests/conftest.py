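import numpy as np
import pytest

import morbmap as m


@pytest.fixture(scope="session")
def egypt():
    return m.egypt_governorates()


@pytest.fixture(scope="session")
def path3():
    """Three-node path graph 1-2-3."""
    return m.AdjacencyGraph.from_edges([1, 2, 3], [(1, 2), (2, 3)])


@pytest.fixture(scope="session")
def small_survey(egypt):
    """A small two-binary-covariate synthetic survey with known truth."""
    truth = m.two_binary_truth(seed=5, n_children=600, graph=egypt)
    return m.generate_survey(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
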