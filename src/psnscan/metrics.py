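"""Topological indices of a threshold network.

Covers the standard characterization battery: degree statistics and the
degree distribution p(k); clustering coefficients c_i, their mean C and the
degree-conditioned profile C(k); shortest-path statistics <d> and diameter D;
node and edge betweenness (Brandes fractional counting, normalized by
N(N-1)/2); degree assortativity Q; greedy box-covering fractal dimension
d_b; and the modularity m_d of a community partition.

Conventions (they matter for reproducibility):

* ``c_i = 0`` for nodes of degree < 2, and C averages over *all* N nodes.
* <d> and D are taken over connected pairs only; components are reported
  alongside so a fragmented graph is never silently averaged.
* Node betweenness excludes path endpoints; multiple shortest paths split
  weight equally.  With the N(N-1)/2 normalization, the normalized edge
  betweenness summed over all edges equals <d> on a connected graph (every
  shortest path of length l crosses l edges) — a useful internal check.
* Degree assortativity is Newman's degree-degree Pearson correlation; it is
  defined as 0 when degenerate (no edges or constant degrees).  Per-node
  relative excess neighbor degrees q_i are exposed separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import networkx as nx

from .errors import (
    PartitionError,
    UndefinedDimensionError,
    UndefinedPathError,
)
from .netscan import NeighborhoodMatrix, ThresholdGraph, neighborhood_matrix

__all__ = [
    "NetworkIndices",
    "degree_stats",
    "clustering",
    "path_stats",
    "betweenness",
    "assortativity",
    "fractal_dimension",
    "modularity",
    "compute_indices",
]

Edge = tuple[str, str]


def _pair_norm(n: int) -> float:
    return n * (n - 1) / 2


def degree_stats(
    G: ThresholdGraph,
) -> tuple[float, int, int, dict[int, int]]:
    """Average degree <k> = 2m/n, min/max degree, and the histogram p(k)."""
    k = G.degrees()
    hist: dict[int, int] = {
        int(d): int(c) for d, c in zip(*np.unique(k, return_counts=True))
    }
    return float(k.mean()), int(k.min()), int(k.max()), hist


def clustering(
    G: ThresholdGraph,
) -> tuple[dict[str, float], float, dict[int, float]]:
    """Per-node clustering c_i, network clustering C, and C(k).

    c_i = edges among neighbors of i / (k_i (k_i - 1) / 2), zero when
    k_i < 2; C is the unweighted mean over all n nodes; C(k) averages c_i
    over nodes of degree k.
    """
    g = G.to_networkx()
    c_i = {node: float(c) for node, c in nx.clustering(g).items()}
    C = float(np.mean([c_i[lab] for lab in G.labels])) if G.n else 0.0
    by_degree: dict[int, list[float]] = {}
    degs = G.degrees()
    for lab, k in zip(G.labels, degs):
        by_degree.setdefault(int(k), []).append(c_i[lab])
    C_k = {k: float(np.mean(v)) for k, v in sorted(by_degree.items())}
    return c_i, C, C_k


def path_stats(
    G: ThresholdGraph, nbhd: NeighborhoodMatrix | None = None
) -> tuple[float, int, list[int]]:
    """Average shortest path <d>, diameter D, and component sizes.

    Averages run over connected pairs only; D is the largest finite
    shortest-path length.  An edgeless graph has no finite path at all.
    """
    if G.m == 0:
        raise UndefinedPathError("no edges: shortest paths undefined")
    if nbhd is None:
        nbhd = neighborhood_matrix(G)
    n = G.n
    iu = np.triu_indices(n, k=1)
    upper = nbhd.entries[iu]
    finite = upper[upper < nbhd.sentinel]
    avg = float(finite.mean())
    diameter = int(finite.max())
    from .netscan import component_sizes

    return avg, diameter, component_sizes(G)


def betweenness(
    G: ThresholdGraph,
) -> tuple[dict[str, float], dict[Edge, float], float, float]:
    """Node and edge betweenness, normalized by N(N-1)/2.

    Brandes accumulation over all unordered pairs with fractional splitting
    across multiple shortest paths; endpoints are not counted for node
    betweenness.  Returns per-node values, per-edge values (keys are sorted
    label pairs), and their averages B_n (over nodes) and B_e (over edges).
    """
    g = G.to_networkx()
    norm = _pair_norm(G.n) if G.n > 1 else 1.0
    node_raw = nx.betweenness_centrality(g, normalized=False, endpoints=False)
    edge_raw = nx.edge_betweenness_centrality(g, normalized=False)
    b_n = {lab: float(v) / norm for lab, v in node_raw.items()}
    b_e = {
        tuple(sorted((u, v))): float(w) / norm for (u, v), w in edge_raw.items()
    }
    B_n = float(np.mean([b_n[lab] for lab in G.labels])) if G.n else 0.0
    B_e = float(np.mean(list(b_e.values()))) if b_e else 0.0
    return b_n, b_e, B_n, B_e


def assortativity(G: ThresholdGraph) -> tuple[float, dict[str, float]]:
    """Degree assortativity Q plus per-node excess neighbor degrees.

    Q is the Pearson correlation of degrees at the two ends of each edge,
    in [-1, 1]; defined as 0 when the correlation is degenerate (no edges,
    or all degrees equal).  q_i = (mean neighbor degree of i - <k>) / <k>
    (0 for isolated nodes) is exposed for completeness.
    """
    g = G.to_networkx()
    degs = G.degrees()
    avg_k = float(degs.mean()) if G.n else 0.0
    q_i: dict[str, float] = {}
    adj = G.adjacency
    for idx, lab in enumerate(G.labels):
        k = degs[idx]
        if k == 0 or avg_k == 0:
            q_i[lab] = 0.0
        else:
            knn = float((adj[idx] * degs).sum()) / k
            q_i[lab] = (knn - avg_k) / avg_k
    if G.m == 0 or len(set(degs.tolist())) == 1:
        return 0.0, q_i
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = nx.degree_assortativity_coefficient(g)
    if not np.isfinite(Q):
        Q = 0.0
    return float(Q), q_i


def box_counts(G: ThresholdGraph) -> dict[int, int]:
    """Greedy box-covering counts N_B(l_B) for box sizes l_B = 1..D.

    A box of size l_B is a node set of diameter < l_B.  The covering is the
    graph-coloring formulation: color the auxiliary graph joining nodes at
    distance >= l_B with first-fit greedy coloring in sorted-label order;
    the number of colors used is N_B(l_B).
    """
    nbhd = neighborhood_matrix(G)
    dist = nbhd.entries
    order = sorted(range(G.n), key=lambda i: G.labels[i])
    counts: dict[int, int] = {}
    iu = np.triu_indices(G.n, k=1)
    diameter = int(dist[iu].max()) if G.n > 1 else 0
    for l_B in range(1, diameter + 1):
        color = np.full(G.n, -1, dtype=int)
        ncolors = 0
        for i in order:
            conflicts = {
                int(color[j])
                for j in range(G.n)
                if color[j] >= 0 and dist[i, j] >= l_B
            }
            c = 0
            while c in conflicts:
                c += 1
            color[i] = c
            ncolors = max(ncolors, c + 1)
        counts[l_B] = ncolors
    return counts


def fractal_dimension(G: ThresholdGraph) -> float:
    """Box-covering fractal dimension d_b.

    Least-squares slope of log N_B(l_B) against log l_B over l_B = 1..D,
    negated.  Requires a connected graph with diameter >= 2; the value
    depends mildly on the greedy covering heuristic, which is fixed
    (sorted-label first-fit) for reproducibility.
    """
    from .netscan import component_sizes

    if G.m == 0 or len(component_sizes(G)) != 1:
        raise UndefinedDimensionError("fractal dimension needs a connected graph")
    counts = box_counts(G)
    if len(counts) < 2:
        raise UndefinedDimensionError("fractal dimension needs diameter >= 2")
    ls = np.log(np.array(sorted(counts)))
    ns = np.log(np.array([counts[l] for l in sorted(counts)]))
    slope = np.polyfit(ls, ns, 1)[0]
    return float(-slope)


def modularity(
    G: ThresholdGraph, communities: Iterable[Iterable[str]]
) -> float:
    """Newman modularity m_d = sum_c (e_cc - a_c^2).

    e_cc is the fraction of edges with both ends in community c and a_c the
    fraction of edge ends attached to c.  The partition must cover every
    node exactly once.  An edgeless graph has m_d = 0 by convention.
    """
    comms = [frozenset(c) for c in communities]
    flat = [lab for c in comms for lab in c]
    if len(flat) != len(set(flat)):
        raise PartitionError("communities overlap")
    if set(flat) != set(G.labels):
        raise PartitionError("communities do not cover the node set")
    m = G.m
    if m == 0:
        return 0.0
    member = {lab: ci for ci, c in enumerate(comms) for lab in c}
    e = np.zeros(len(comms))
    a = np.zeros(len(comms))
    for u, v in G.edges():
        cu, cv = member[u], member[v]
        if cu == cv:
            e[cu] += 1
        a[cu] += 1
        a[cv] += 1
    e /= m
    a /= 2 * m
    return float((e - a**2).sum())


@dataclass(frozen=True)
class NetworkIndices:
    """The full index battery for one threshold network."""

    sigma: int
    n: int
    m: int
    avg_degree: float
    degree_min: int
    degree_max: int
    degree_hist: dict[int, int]
    clustering_per_node: dict[str, float] = field(repr=False)
    network_clustering: float = 0.0
    clustering_by_degree: dict[int, float] = field(default_factory=dict)
    avg_shortest_path: float = float("nan")
    diameter: int = 0
    node_betweenness: dict[str, float] = field(default_factory=dict, repr=False)
    edge_betweenness: dict[Edge, float] = field(default_factory=dict, repr=False)
    avg_node_betweenness: float = 0.0
    avg_edge_betweenness: float = 0.0
    assortativity: float = 0.0
    q_i: dict[str, float] = field(default_factory=dict, repr=False)
    fractal_dimension: float | None = None
    connected: bool = True
    component_sizes: tuple[int, ...] = ()

    def report(self) -> dict:
        """JSON-ready report grouped the way practitioners read it:
        connectivity, assortativity, distance, cluster, auto-similarity."""
        return {
            "sigma": self.sigma,
            "order_n": self.n,
            "size_m": self.m,
            "connectivity": {
                "avg_degree": self.avg_degree,
                "degree_min": self.degree_min,
                "degree_max": self.degree_max,
                "degree_hist": {str(k): v for k, v in self.degree_hist.items()},
            },
            "assortativity": {"Q": self.assortativity},
            "distance": {
                "avg_shortest_path": self.avg_shortest_path,
                "diameter": self.diameter,
                "avg_node_betweenness": self.avg_node_betweenness,
                "avg_edge_betweenness": self.avg_edge_betweenness,
            },
            "cluster": {
                "network_clustering": self.network_clustering,
                "clustering_by_degree": {
                    str(k): v for k, v in self.clustering_by_degree.items()
                },
            },
            "auto_similarity": {"fractal_dimension": self.fractal_dimension},
            "components": {
                "connected": self.connected,
                "sizes": list(self.component_sizes),
            },
        }

    def to_json(self, path: str | Path, extra: Mapping | None = None) -> None:
        payload = self.report()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def compute_indices(G: ThresholdGraph) -> NetworkIndices:
    """Compute every index for *G* in one pass.

    Fractal dimension is set to None when undefined (disconnected graph or
    diameter < 2) rather than raising, so a full report can always be
    produced.
    """
    avg_k, kmin, kmax, hist = degree_stats(G)
    c_i, C, C_k = clustering(G)
    avg_d, diam, comps = path_stats(G) if G.m else (float("nan"), 0, [1] * G.n)
    b_n, b_e, B_n, B_e = betweenness(G)
    Q, q_i = assortativity(G)
    try:
        d_b: float | None = fractal_dimension(G)
    except UndefinedDimensionError:
        d_b = None
    return NetworkIndices(
        sigma=G.sigma,
        n=G.n,
        m=G.m,
        avg_degree=avg_k,
        degree_min=kmin,
        degree_max=kmax,
        degree_hist=hist,
        clustering_per_node=c_i,
        network_clustering=C,
        clustering_by_degree=C_k,
        avg_shortest_path=avg_d,
        diameter=diam,
        node_betweenness=b_n,
        edge_betweenness=b_e,
        avg_node_betweenness=B_n,
        avg_edge_betweenness=B_e,
        assortativity=Q,
        q_i=q_i,
        fractal_dimension=d_b,
        connected=len(comps) == 1,
        component_sizes=tuple(comps),
    )
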