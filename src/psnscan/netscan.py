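"""Threshold-network families, neighborhood matrices, and the critical scan.

From one symmetrized similarity matrix ``S`` a family of 101 unweighted
graphs is built, one per integer threshold ``sigma`` in ``[0, 100]``: nodes
are sequences, and an edge joins ``i`` and ``j`` (``i != j``) exactly when
``S_ij >= sigma``.  Raising sigma only removes edges, so the family
interpolates from the complete graph (sigma = 0) to the empty graph.

Each graph is summarized by its *neighborhood matrix* ``M-hat`` whose (i, j)
entry is the shortest-path length between i and j (0 on the diagonal; a
sentinel, by default n, for unreachable pairs).  Consecutive graphs are
compared with the normalized L1 distance

    delta(sigma, sigma + 1) = sum_{i<j} |Mhat_a - Mhat_b| / (n (n-1) / 2),

a true metric on neighborhood matrices.  Sharp peaks of delta mark
thresholds where the topology reorganizes; the global maximum defines the
*critical threshold* sigma_c and the critical network analyzed downstream.
Fragmentation events move entries from small path lengths to the sentinel
and therefore dominate delta, which is exactly the transition the scan is
meant to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import AlignmentError, SizeError, StateError
from .simio import SimilarityMatrix

__all__ = [
    "ThresholdGraph",
    "NeighborhoodMatrix",
    "DistanceProfile",
    "build_network",
    "neighborhood_matrix",
    "network_distance",
    "scan",
]


@dataclass(frozen=True)
class ThresholdGraph:
    """An unweighted similarity network at one integer threshold.

    ``adjacency`` is the binary matrix M with ``m_ij = 1`` iff
    ``S_ij >= sigma`` for ``i != j``; symmetric with a zero diagonal.
    """

    sigma: int
    labels: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> int:
        """Edge count."""
        return int(np.triu(self.adjacency, k=1).sum())

    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.labels[i], self.labels[j]) for i, j in zip(ii, jj)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges())
        return g

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass(frozen=True)
class NeighborhoodMatrix:
    """All-pairs shortest-path lengths with a sentinel for unreachable pairs.

    Equivalent to M-hat = sum_l l * M(l) where M(l) indicates pairs at
    distance exactly l, extended with ``sentinel`` (default n, exceeding any
    finite distance) where no path exists.
    """

    labels: tuple[str, ...]
    entries: np.ndarray = field(repr=False)
    sentinel: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=int))

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(["", *self.labels])]
        for label, row in zip(self.labels, self.entries):
            lines.append("\t".join([label, *(str(int(v)) for v in row)]))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class DistanceProfile:
    """delta(sigma, sigma+1) for sigma = 0..99, plus the critical threshold.

    ``sigma_c`` attains the maximum of ``delta_values`` (smallest sigma on
    ties).  ``secondary_peaks`` are the other strict local maxima of the
    series, ordered by descending delta.
    """

    sigma_values: tuple[int, ...]
    delta_values: tuple[float, ...]
    sigma_c: int
    secondary_peaks: tuple[tuple[int, float], ...]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["sigma\tdelta"]
        lines += [
            f"{s}\t{d!r}" for s, d in zip(self.sigma_values, self.delta_values)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def summary(self) -> dict:
        return {
            "sigma_c": self.sigma_c,
            "delta_at_sigma_c": self.delta_values[
                self.sigma_values.index(self.sigma_c)
            ],
            "peaks": [
                {"sigma": s, "delta": d} for s, d in self.secondary_peaks
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def build_network(S: SimilarityMatrix, sigma: int) -> ThresholdGraph:
    """Threshold *S* at *sigma*: edge (i, j) present iff ``S_ij >= sigma``.

    Requires a symmetrized matrix (directional scores would make the edge
    relation ambiguous).  Self-loops are never created.
    """
    if not S.symmetrized:
        raise StateError("similarity matrix must be symmetrized first")
    if not 0 <= sigma <= 100:
        raise ValueError(f"sigma must be in [0, 100], got {sigma}")
    adjacency = (S.values >= sigma).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return ThresholdGraph(int(sigma), S.labels, adjacency)


def neighborhood_matrix(
    G: ThresholdGraph, sentinel: int | None = None
) -> NeighborhoodMatrix:
    """BFS all-pairs shortest-path lengths; unreachable pairs get *sentinel*
    (default: n, larger than any possible finite distance)."""
    n = G.n
    if sentinel is None:
        sentinel = n
    dist = shortest_path(
        csr_matrix(G.adjacency), method="D", unweighted=True, directed=False
    )
    dist[np.isinf(dist)] = sentinel
    entries = dist.astype(int)
    np.fill_diagonal(entries, 0)
    return NeighborhoodMatrix(G.labels, entries, sentinel=int(sentinel))


def network_distance(A: NeighborhoodMatrix, B: NeighborhoodMatrix) -> float:
    """Normalized L1 distance between two neighborhood matrices:
    ``sum_{i<j} |A_ij - B_ij| / (n (n-1) / 2)``.

    Zero iff the matrices are equal; symmetric; satisfies the triangle
    inequality (it is a scaled L1 metric on the upper-triangle entries).
    """
    if set(A.labels) != set(B.labels):
        raise AlignmentError("neighborhood matrices are over different node sets")
    b_entries = B.entries
    if A.labels != B.labels:
        order = [B.labels.index(lab) for lab in A.labels]
        b_entries = b_entries[np.ix_(order, order)]
    n = A.n
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    diff = np.abs(A.entries[iu] - b_entries[iu]).sum()
    return float(diff) / (n * (n - 1) / 2)


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima (endpoints compared one-sided)."""
    out = []
    k = len(values)
    for i in range(k):
        left_ok = i == 0 or values[i] > values[i - 1]
        right_ok = i == k - 1 or values[i] > values[i + 1]
        if left_ok and right_ok:
            out.append(i)
    return out


def scan(S: SimilarityMatrix, sentinel: int | None = None) -> DistanceProfile:
    """Scan all 101 thresholds and locate the critical one.

    Computes delta(sigma, sigma+1) for sigma = 0..99 from consecutive
    neighborhood matrices; ``sigma_c`` is the argmax (smallest on ties) and
    the other strict local maxima are reported as secondary peaks sorted by
    descending delta (ties by ascending sigma).
    """
    if not S.symmetrized:
        raise StateError("similarity matrix must be symmetrized first")
    if S.n < 2:
        raise SizeError(f"need at least 2 sequences, got {S.n}")
    mats = [
        neighborhood_matrix(build_network(S, sigma), sentinel=sentinel)
        for sigma in range(101)
    ]
    deltas = np.array(
        [network_distance(mats[s], mats[s + 1]) for s in range(100)]
    )
    sigma_c = int(np.argmax(deltas))  # argmax takes the first = smallest sigma
    peaks = [
        (i, float(deltas[i]))
        for i in _local_maxima(deltas)
        if i != sigma_c and deltas[i] > 0
    ]
    peaks.sort(key=lambda p: (-p[1], p[0]))
    return DistanceProfile(
        sigma_values=tuple(range(100)),
        delta_values=tuple(float(d) for d in deltas),
        sigma_c=sigma_c,
        secondary_peaks=tuple(peaks),
    )


def component_sizes(G: ThresholdGraph) -> list[int]:
    """Sizes of connected components, largest first."""
    ncomp, memb = connected_components(csr_matrix(G.adjacency), directed=False)
    return sorted(np.bincount(memb).tolist(), reverse=True)
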