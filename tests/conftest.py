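import numpy as np
import pytest

from graphtexture.cooccurrence import CooccurrenceMatrix, ProbabilityMatrix
from graphtexture.graph import NodeWeightedGraph


@pytest.fixture
def triangle_graph():
    """Triangle with levels (1, 1, 2): the smallest non-trivial level graph."""
    return NodeWeightedGraph(
        ["a", "b", "c"],
        [("a", "b"), ("b", "c"), ("a", "c")],
        weights={"a": 1, "b": 1, "c": 2},
    )


@pytest.fixture
def triangle_prob(triangle_graph):
    from graphtexture.cooccurrence import count_cooccurrence, normalize

    return normalize(count_cooccurrence(triangle_graph))


@pytest.fixture
def antidiagonal_prob():
    """p = [[0, .5], [.5, 0]]: perfectly anti-correlated 2-level matrix."""
    return ProbabilityMatrix(levels=(1, 2), p=np.array([[0.0, 0.5], [0.5, 0.0]]))


def random_level_graph(rng, max_nodes=20, max_levels=6, directed=False):
    """A random simple graph with random integer levels, for oracle checks."""
    n = int(rng.integers(2, max_nodes + 1))
    ng = int(rng.integers(1, max_levels + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        rng_j = range(n) if directed else range(i + 1, n)
        for j in rng_j:
            if i != j and rng.random() < 0.3:
                edges.append((nodes[i], nodes[j]))
    if not edges:
        edges = [(nodes[0], nodes[1])]
    levels = {nd: int(l) for nd, l in zip(nodes, rng.integers(1, ng + 1, size=n))}
    return NodeWeightedGraph(nodes, edges, directed=directed, weights=levels), ng


def brute_force_counts(graph, n_levels, mode):
    """Independent oracle: double loop over the full adjacency matrix."""
    idx = {nd: k for k, nd in enumerate(graph.nodes)}
    n = graph.n_nodes
    A = np.zeros((n, n), dtype=int)
    for u, v in graph.edges:
        A[idx[u], idx[v]] = 1
        if mode == "undirected":
            A[idx[v], idx[u]] = 1
    lv = np.array([int(graph.weights[nd]) for nd in graph.nodes])
    C = np.zeros((n_levels, n_levels), dtype=int)
    for a in range(n):
        for b in range(n):
            if A[a, b]:
                C[lv[a] - 1, lv[b] - 1] += 1
    return C


def random_probability_matrix(rng, max_levels=8):
    ng = int(rng.integers(2, max_levels + 1))
    raw = rng.random((ng, ng))
    # zero some cells so sparse matrices are exercised too
    raw[rng.random((ng, ng)) < 0.3] = 0.0
    if raw.sum() == 0:
        raw[0, 0] = 1.0
    return ProbabilityMatrix(levels=tuple(range(1, ng + 1)), p=raw / raw.sum())
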