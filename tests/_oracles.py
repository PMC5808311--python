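"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (BFS by hand, explicit enumeration of
all shortest paths, double-loop modularity tallies) and shares no code with
the package under test.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def bfs_distances(nodes, edges):
    """All-pairs shortest-path lengths by repeated hand-rolled BFS.

    Returns {(u, v): length} for every ordered pair with a path, including
    (u, u): 0.
    """
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {}
    for source in nodes:
        dist[(source, source)] = 0
        seen = {source: 0}
        queue = deque([source])
        while queue:
            x = queue.popleft()
            for y in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + 1
                    queue.append(y)
        for target, d in seen.items():
            dist[(source, target)] = d
    return dist


def all_shortest_paths(nodes, edges, s, t):
    """Every shortest s-t path as a node sequence (exponential; tiny graphs
    only)."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = bfs_distances(nodes, edges)
    if (s, t) not in dist:
        return []
    target_len = dist[(s, t)]

    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        used = len(path) - 1  # edges consumed so far
        for y in adj[last]:
            on_shortest = (
                (s, y) in dist
                and (y, t) in dist
                and dist[(s, y)] == used + 1
                and dist[(s, y)] + dist[(y, t)] == target_len
            )
            if on_shortest:
                extend(path + [y])

    extend([s])
    return paths


def brute_betweenness(nodes, edges):
    """Fractional node/edge betweenness by explicit shortest-path
    enumeration, normalized by n(n-1)/2.  Endpoints are not counted for
    nodes."""
    nodes = list(nodes)
    n = len(nodes)
    norm = n * (n - 1) / 2 if n > 1 else 1.0
    node_b = {u: 0.0 for u in nodes}
    edge_b = {tuple(sorted(e)): 0.0 for e in edges}
    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(nodes, edges, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for path in paths:
            for interior in path[1:-1]:
                node_b[interior] += w
            for a, b in zip(path, path[1:]):
                edge_b[tuple(sorted((a, b)))] += w
    return (
        {u: v / norm for u, v in node_b.items()},
        {e: v / norm for e, v in edge_b.items()},
    )


def brute_modularity(nodes, edges, communities):
    """m_d = sum_c (e_cc - a_c^2) tallied with plain loops."""
    m = len(edges)
    if m == 0:
        return 0.0
    member = {}
    for ci, comm in enumerate(communities):
        for u in comm:
            member[u] = ci
    total = 0.0
    for ci in range(len(list(communities))):
        e_cc = sum(1 for u, v in edges if member[u] == ci and member[v] == ci) / m
        ends = sum((member[u] == ci) + (member[v] == ci) for u, v in edges) / (2 * m)
        total += e_cc - ends**2
    return total


def brute_clustering(nodes, edges):
    """Per-node clustering coefficient by neighbor-pair counting."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for u in nodes:
        k = len(adj[u])
        if k < 2:
            out[u] = 0.0
            continue
        links = sum(
            1 for a, b in combinations(sorted(adj[u]), 2) if b in adj[a]
        )
        out[u] = links / (k * (k - 1) / 2)
    return out
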