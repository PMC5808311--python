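import numpy as np
import pytest

from psnscan import SimilarityMatrix, ThresholdGraph, build_network


def matrix_from_upper(labels, pairs, default=0.0, symmetrized=True):
    """Build a SimilarityMatrix from {(a, b): score} over unordered pairs."""
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    vals = np.full((n, n), default, dtype=float)
    np.fill_diagonal(vals, 100.0)
    for (a, b), score in pairs.items():
        vals[idx[a], idx[b]] = score
        vals[idx[b], idx[a]] = score
    return SimilarityMatrix(tuple(labels), vals, symmetrized=symmetrized)


def graph_from_edges(labels, edges, sigma=50):
    """A ThresholdGraph with exactly the given edges."""
    pairs = {tuple(sorted(e)): 100.0 for e in edges}
    return build_network(matrix_from_upper(labels, pairs), sigma)


def nx_to_threshold_graph(g, sigma=50):
    labels = sorted(str(u) for u in g.nodes)
    edges = [(str(u), str(v)) for u, v in g.edges]
    return graph_from_edges(labels, edges, sigma=sigma)


@pytest.fixture
def two_triangles_bridge():
    """Two K3s (x1 x2 x3, y1 y2 y3) joined by the bridge x3-y1."""
    labels = ["x1", "x2", "x3", "y1", "y2", "y3"]
    edges = [
        ("x1", "x2"), ("x1", "x3"), ("x2", "x3"),
        ("y1", "y2"), ("y1", "y3"), ("y2", "y3"),
        ("x3", "y1"),
    ]
    return graph_from_edges(labels, edges)


@pytest.fixture
def path_abc():
    """The 3-node path a-b-c."""
    return graph_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def planted_three_blocks():
    """The standard planted benchmark: 3 blocks of 12, 80/30 means, sd 5."""
    from psnscan.synth import PlantedSpec, planted_blocks

    return planted_blocks(
        PlantedSpec(block_sizes=(12, 12, 12), mu_in=80, mu_out=30, sd=5, seed=7)
    )
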