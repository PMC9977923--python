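import numpy as np
import pytest

from modanneal import WeightedGraph


def graph_from_edges(n, edges, weights=None):
    A = np.zeros((n, n))
    for idx, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[idx]
        A[i, j] = A[j, i] = w
    return WeightedGraph([str(i) for i in range(n)], A, weighted=weights is not None)


def random_graph(rng, n, p=0.5, weighted=False):
    """Erdos-Renyi draw, resampled until it has at least one edge."""
    while True:
        upper = np.triu(rng.random((n, n)) < p, k=1).astype(float)
        if upper.sum() == 0:
            continue
        if weighted:
            upper *= rng.uniform(0.5, 1.5, size=upper.shape)
        A = upper + upper.T
        return WeightedGraph([str(i) for i in range(n)], A, weighted=weighted)


@pytest.fixture
def single_edge():
    return graph_from_edges(2, [(0, 1)])


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def two_triangles():
    """Two disconnected 3-cliques."""
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def bridged_triangles():
    """Two 3-cliques joined by a single bridge edge; optimal 2-split Q = 5/14."""
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
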