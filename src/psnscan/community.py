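"""Newman-Girvan community detection and classification comparison.

The divisive algorithm removes, one at a time, the edge with the largest
edge betweenness in the *current* graph (full recomputation after every
removal; ties broken by the lexicographically smallest sorted endpoint
pair, which makes the whole procedure deterministic).  Every time a removal
disconnects a component, the split is recorded; the ordered removal history
induces a binary dendrogram over the node set, exactly analogous to a
phylogenetic tree with clades replaced by network communities.

Edge betweenness inside the removal loop is evaluated with igraph's C
implementation; the removal policy, event log, dendrogram assembly,
partition selection, and congruence index are implemented here.

Partition selection automates the paper-and-pencil step of reading a
community structure off a dendrogram: among all component configurations
visited during removal (including the initial one), keep the one with the
largest modularity (ties: fewer communities, then the earlier stage).
A fixed community count can be requested instead.

The congruence index G(phi, psi) compares two classifications of (possibly
partially) overlapping organism sets: restrict both to the R common
organisms, match communities one-to-one to maximize co-assignment
(Hungarian algorithm on the overlap-count matrix), and report
G = 100 * Q / R where Q organisms fall in matched pairs.  Identical
partitions give G = 100 regardless of community labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import igraph as ig
from scipy.optimize import linear_sum_assignment

from .errors import NoOverlapError, NotABranchError, PartitionError, SizeError
from .metrics import modularity
from .netscan import ThresholdGraph

__all__ = [
    "RemovalEvent",
    "Branch",
    "Dendrogram",
    "Partition",
    "CongruenceResult",
    "newman_girvan",
    "best_partition",
    "fixed_k_partition",
    "removed_edges_to_isolate",
    "congruence",
    "leaf_order",
    "to_newick",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class RemovalEvent:
    """One edge removal: which edge, its betweenness (normalized by
    N(N-1)/2) at the moment of removal, and the split it caused, if any."""

    step: int
    edge: tuple[str, str]
    betweenness_at_removal: float
    split_created: tuple[frozenset[str], frozenset[str]] | None = None


@dataclass
class Branch:
    """A dendrogram branch: a node set that was a connected component at
    some stage of removal.  ``created_at`` is the removal step that created
    it (0 for initial components and the root)."""

    members: frozenset[str]
    created_at: int
    children: tuple["Branch", "Branch"] | None = None

    def walk(self) -> Iterable["Branch"]:
        yield self
        if self.children is not None:
            for child in self.children:
                yield from child.walk()


@dataclass(frozen=True)
class Partition:
    """Disjoint node sets covering the graph, with their modularity."""

    communities: tuple[frozenset[str], ...]
    modularity: float = float("nan")

    @property
    def k(self) -> int:
        return len(self.communities)

    def membership(self) -> dict[str, int]:
        return {lab: i for i, c in enumerate(self.communities) for lab in c}

    def to_tsv(self, path: str | Path) -> None:
        lines = ["label\tcommunity_id"]
        for i, comm in enumerate(self.communities, start=1):
            for lab in sorted(comm):
                lines.append(f"{lab}\t{i}")
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def from_tsv(path: str | Path) -> "Partition":
        groups: dict[str, set[str]] = {}
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            lab, cid = line.split("\t")
            groups.setdefault(cid, set()).add(lab)
        return Partition(tuple(frozenset(g) for g in groups.values()))

    @staticmethod
    def from_mapping(mapping: Mapping[str, object]) -> "Partition":
        groups: dict[object, set[str]] = {}
        for lab, cid in mapping.items():
            groups.setdefault(cid, set()).add(lab)
        return Partition(
            tuple(frozenset(groups[k]) for k in sorted(groups, key=str))
        )


@dataclass(frozen=True)
class CongruenceResult:
    """Outcome of comparing two classifications of overlapping organisms."""

    R: int
    Q_matched: int
    G: float


@dataclass(frozen=True)
class Dendrogram:
    """Ordered removal history plus the induced binary split tree."""

    root: Branch
    events: tuple[RemovalEvent, ...]
    initial_components: tuple[frozenset[str], ...]

    @property
    def labels(self) -> frozenset[str]:
        return self.root.members

    def branches(self) -> list[Branch]:
        return list(self.root.walk())

    def branch_sets(self) -> set[frozenset[str]]:
        return {b.members for b in self.root.walk()}

    def find(self, members: frozenset[str]) -> Branch:
        for b in self.root.walk():
            if b.members == members:
                return b
        raise NotABranchError(f"{sorted(members)} is not a dendrogram branch")

    def events_to_json(self, path: str | Path) -> None:
        payload = [
            {
                "step": ev.step,
                "edge": list(ev.edge),
                "betweenness": ev.betweenness_at_removal,
                "split": (
                    None
                    if ev.split_created is None
                    else [sorted(s) for s in ev.split_created]
                ),
            }
            for ev in self.events
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _chain_initial_components(
    root_members: frozenset[str], comps: list[frozenset[str]]
) -> tuple[Branch, dict[frozenset[str], Branch]]:
    """Attach initially disconnected components under a single root by a
    deterministic chain of step-0 splits (largest component first, ties by
    smallest label)."""
    root = Branch(root_members, created_at=0)
    leaves: dict[frozenset[str], Branch] = {}
    comps = sorted(comps, key=lambda c: (-len(c), min(c)))
    node = root
    for i, comp in enumerate(comps):
        if i == len(comps) - 1:
            leaves[node.members] = node
            break
        rest = frozenset(node.members - comp)
        left = Branch(comp, created_at=0)
        right = Branch(rest, created_at=0)
        node.children = (left, right)
        leaves[comp] = left
        node = right
    return root, leaves


def newman_girvan(G: ThresholdGraph) -> Dendrogram:
    """Run the full divisive edge-removal procedure on *G*.

    Removes one edge per iteration (the largest-betweenness edge, ties by
    lexicographically smallest sorted endpoint pair) with full betweenness
    recomputation, until no edges remain; the event count equals the
    initial edge count and the final state is all-singleton.
    """
    labels = list(G.labels)
    n = len(labels)
    norm = n * (n - 1) / 2 if n > 1 else 1.0
    li = {lab: i for i, lab in enumerate(labels)}
    g = ig.Graph(n=n, edges=[(li[u], li[v]) for u, v in G.edges()])

    # current components as frozensets of label indices
    comps = [frozenset(c) for c in g.connected_components()]
    initial = [frozenset(labels[i] for i in c) for c in comps]
    root, branch_of = _chain_initial_components(frozenset(labels), initial)

    comp_of: dict[int, frozenset[int]] = {v: c for c in comps for v in c}
    events: list[RemovalEvent] = []
    step = 0
    while g.ecount() > 0:
        step += 1
        eb = g.edge_betweenness()
        edgelist = g.get_edgelist()
        best = max(eb)
        tol = _TIE_TOL * max(1.0, abs(best))
        candidates = [
            i for i, b in enumerate(eb) if best - b <= tol
        ]
        # deterministic tie-break: smallest sorted endpoint label pair
        def _key(eidx: int) -> tuple[str, str]:
            a, b = edgelist[eidx]
            return tuple(sorted((labels[a], labels[b])))  # type: ignore[return-value]

        chosen = min(candidates, key=_key)
        u, v = edgelist[chosen]
        edge_labels = tuple(sorted((labels[u], labels[v])))
        g.delete_edges([chosen])

        split = None
        reach_u = frozenset(g.subcomponent(u, mode="all"))
        if v not in reach_u:
            old = comp_of[u]
            part_u = reach_u
            part_v = frozenset(old - reach_u)
            for x in part_u:
                comp_of[x] = part_u
            for x in part_v:
                comp_of[x] = part_v
            set_u = frozenset(labels[i] for i in part_u)
            set_v = frozenset(labels[i] for i in part_v)
            split = tuple(sorted((set_u, set_v), key=lambda s: (-len(s), min(s))))
            parent_set = frozenset(labels[i] for i in old)
            parent = branch_of.pop(parent_set)
            left = Branch(split[0], created_at=step)
            right = Branch(split[1], created_at=step)
            parent.children = (left, right)
            branch_of[split[0]] = left
            branch_of[split[1]] = right
        events.append(
            RemovalEvent(
                step=step,
                edge=edge_labels,  # type: ignore[arg-type]
                betweenness_at_removal=float(eb[chosen]) / norm,
                split_created=split,  # type: ignore[arg-type]
            )
        )
    return Dendrogram(
        root=root,
        events=tuple(events),
        initial_components=tuple(
            sorted(initial, key=lambda c: (-len(c), min(c)))
        ),
    )


def _configurations(
    d: Dendrogram,
) -> Iterable[tuple[int, tuple[frozenset[str], ...]]]:
    """Yield (stage, component configuration) at stage 0 and after every
    split event.  Stage = the event step that produced the configuration."""
    comps = {c for c in d.initial_components}
    yield 0, tuple(sorted(comps, key=lambda c: (-len(c), min(c))))
    for ev in d.events:
        if ev.split_created is None:
            continue
        parent = ev.split_created[0] | ev.split_created[1]
        comps.discard(parent)
        comps.update(ev.split_created)
        yield ev.step, tuple(sorted(comps, key=lambda c: (-len(c), min(c))))


def best_partition(d: Dendrogram, G: ThresholdGraph) -> Partition:
    """Maximum-modularity configuration among those visited during removal.

    Ties prefer fewer communities, then the earlier stage.  Always at least
    as good as the trivial single-community partition (modularity 0 for a
    connected graph), which is itself a candidate.
    """
    best: tuple[float, int, int] | None = None
    best_cfg: tuple[frozenset[str], ...] = ()
    for stage, cfg in _configurations(d):
        md = modularity(G, cfg)
        key = (-md, len(cfg), stage)
        if best is None or key < best:
            best = key
            best_cfg = cfg
    return Partition(best_cfg, modularity=-best[0])


def fixed_k_partition(d: Dendrogram, G: ThresholdGraph, k: int) -> Partition:
    """First configuration during removal with exactly *k* communities."""
    for _, cfg in _configurations(d):
        if len(cfg) == k:
            return Partition(cfg, modularity=modularity(G, cfg))
    raise SizeError(
        f"no configuration with {k} communities (initial count is "
        f"{len(d.initial_components)})"
    )


def removed_edges_to_isolate(d: Dendrogram, community: Iterable[str]) -> int:
    """Removals needed, from the intact network, until *community* first
    becomes a maximal connected component (inclusive of the isolating
    event); 0 if it already is one."""
    target = frozenset(community)
    if target == d.labels or target in set(d.initial_components):
        return 0
    for ev in d.events:
        if ev.split_created is not None and target in ev.split_created:
            return ev.step
    raise NotABranchError(
        f"{sorted(target)} never occurs as a connected component"
    )


def congruence(P1: Partition, P2: Partition) -> CongruenceResult:
    """Congruence index between two classifications.

    Restrict both partitions to the R organisms they share, find the
    maximum-cardinality one-to-one matching between communities, and
    report G = 100 * Q / R where Q organisms are co-assigned under the
    matching.  Symmetric in its arguments; G = 100 iff the matched
    communities split the common organisms identically.
    """
    labels1 = {lab for c in P1.communities for lab in c}
    labels2 = {lab for c in P2.communities for lab in c}
    common = labels1 & labels2
    R = len(common)
    if R == 0:
        raise NoOverlapError("classifications share no organisms")
    c1 = [c & common for c in P1.communities if c & common]
    c2 = [c & common for c in P2.communities if c & common]
    overlap = np.array([[len(a & b) for b in c2] for a in c1])
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    Q = int(overlap[rows, cols].sum())
    return CongruenceResult(R=R, Q_matched=Q, G=100.0 * Q / R)


def leaf_order(d: Dendrogram) -> list[str]:
    """Depth-first leaf ordering (children larger-set-first, ties by sorted
    labels).  Reordering a neighborhood matrix by this ordering exposes the
    community block structure as contiguous diagonal blocks."""
    order: list[str] = []

    def visit(b: Branch) -> None:
        if b.children is None:
            order.extend(sorted(b.members))
            return
        kids = sorted(
            b.children, key=lambda c: (-len(c.members), tuple(sorted(c.members)))
        )
        for child in kids:
            visit(child)

    visit(d.root)
    return order


def _newick_label(text: str) -> str:
    if any(ch in text for ch in " ()[]:;,'\t\n"):
        return "'" + text.replace("'", "''") + "'"
    return text


def to_newick(
    d: Dendrogram,
    supports: Mapping[frozenset[str], float] | None = None,
) -> str:
    """Serialize the dendrogram as a binary Newick string.

    Internal node labels carry branch support percentages when provided;
    branch lengths are removal-step differences between a branch and its
    parent (cosmetic — they order splits, nothing more).
    """

    def render(b: Branch, parent_step: int) -> str:
        length = max(b.created_at - parent_step, 0)
        if b.children is None:
            if len(b.members) == 1:
                name = _newick_label(next(iter(b.members)))
            else:  # unresolved multi-member leaf (never split)
                name = _newick_label("|".join(sorted(b.members)))
            return f"{name}:{length}"
        kids = sorted(
            b.children, key=lambda c: (-len(c.members), tuple(sorted(c.members)))
        )
        inner = ",".join(render(k, b.created_at) for k in kids)
        label = ""
        if supports is not None and b.members in supports:
            label = f"{supports[b.members]:g}"
        return f"({inner}){label}:{length}"

    return render(d.root, 0) + ";"
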