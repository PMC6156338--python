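import warnings

import numpy as np
import pytest

import graphpam as gp


@pytest.fixture(scope="session")
def two_node():
    return gp.WeightedGraph(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture(scope="session")
def two_node_spectrum(two_node):
    return gp.build_laplacian(two_node)


@pytest.fixture(scope="session")
def single_node_spectrum():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gp.build_laplacian(gp.WeightedGraph(np.zeros((1, 1))))


@pytest.fixture(scope="session")
def random_graph4():
    """Small dense random weighted graph (connected, N = 4)."""
    rng = np.random.default_rng(42)
    W = rng.uniform(0.2, 1.0, (4, 4))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return gp.WeightedGraph(W)


@pytest.fixture(scope="session")
def random_graph4_spectrum(random_graph4):
    return gp.build_laplacian(random_graph4)


@pytest.fixture(scope="session")
def path3():
    """3-node path graph with unit weights."""
    W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return gp.WeightedGraph(W)


@pytest.fixture(scope="session")
def fixture_suite():
    from graphpam.fixtures import generate_fixtures

    return generate_fixtures(seed=2024)
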