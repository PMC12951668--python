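"""ε-neighborhood graphs (Vietoris–Rips 1-skeletons), Prim minimum spanning
trees, root-to-node chronologies, rank-based composites, and tree comparison.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from codechron.complexity_space import DistanceMatrix
from codechron.complexity_metrics import MetricsTable


class TreeError(ValueError):
    pass


Edge = tuple[str, str]


def _norm_edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class NeighborGraph:
    """1-skeleton of the Vietoris–Rips complex at scale eps_total: an edge is
    present iff d_ij <= eps_total. Higher simplices are implicit cliques and
    never materialized."""

    labels: list[str]
    edges: dict[Edge, float]
    eps_per_dim: float
    eps_total: float

    @property
    def n_components(self) -> int:
        parent = {l: l for l in self.labels}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        return len({find(l) for l in self.labels})

    def is_connected(self) -> bool:
        return self.n_components == 1


def build_neighbor_graph(
    dm: DistanceMatrix, eps_per_dim: float, dim: int | None = None
) -> NeighborGraph:
    """ε-graph over the distance matrix. ``eps_total = eps_per_dim × dim``
    (linear scaling); pass ``dim=None`` to treat eps_per_dim as the total ε.
    Masked pairs never produce edges."""
    if eps_per_dim <= 0:
        raise TreeError("eps must be positive")
    eps_total = eps_per_dim * dim if dim is not None else eps_per_dim
    edges: dict[Edge, float] = {}
    for i, j in dm.upper_pairs():
        if dm.mask[i, j]:
            continue
        if dm.d[i, j] <= eps_total:
            edges[_norm_edge(dm.labels[i], dm.labels[j])] = float(dm.d[i, j])
    return NeighborGraph(list(dm.labels), edges, eps_per_dim, eps_total)


def min_connectivity_eps(
    dm: DistanceMatrix, dim: int | None = None, grid_step: float = 0.01
) -> float:
    """Smallest grid multiple of ``grid_step`` (in per-dimension units when
    ``dim`` is given) at which the ε-graph becomes fully connected."""
    if grid_step <= 0:
        raise TreeError("grid_step must be positive")
    eps = grid_step
    while True:
        g = build_neighbor_graph(dm, eps, dim)
        if g.is_connected():
            return eps
        eps += grid_step
        if eps > dm.d.max() * (dim or 1) + grid_step:
            # complete graph reached; connectivity only fails on masked pairs
            raise TreeError("graph cannot be connected (masked pairs isolate nodes)")


@dataclass
class SpanningTree:
    """Undirected weighted tree; ``edges`` maps unordered label pairs to
    weights."""

    labels: list[str]
    edges: dict[Edge, float]
    root: str | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.edges) != n - 1:
            raise TreeError(f"tree on {n} nodes needs {n - 1} edges, got {len(self.edges)}")
        # connectivity + acyclicity via union-find
        parent = {l: l for l in self.labels}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.edges:
            if a not in parent or b not in parent:
                raise TreeError(f"edge ({a},{b}) uses unknown label")
            ra, rb = find(a), find(b)
            if ra == rb:
                raise TreeError(f"cycle introduced by edge ({a},{b})")
            parent[ra] = rb
        if self.root is not None and self.root not in self.labels:
            raise TreeError(f"root {self.root!r} not among labels")

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        adj: dict[str, list[tuple[str, float]]] = {l: [] for l in self.labels}
        for (a, b), w in self.edges.items():
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj

    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.edges)


def prim_mst(graph: NeighborGraph) -> SpanningTree:
    """Prim's algorithm with deterministic lexicographic tie-breaking.

    With all-distinct weights this is the unique global MST; ties are broken
    by (weight, label, label) heap order.
    """
    if not graph.is_connected():
        raise TreeError(
            "neighbor graph is disconnected; increase eps before computing the MST"
        )
    adj: dict[str, list[tuple[float, str]]] = {l: [] for l in graph.labels}
    for (a, b), w in graph.edges.items():
        adj[a].append((w, b))
        adj[b].append((w, a))

    start = min(graph.labels)
    in_tree = {start}
    heap: list[tuple[float, str, str]] = []
    for w, v in adj[start]:
        heapq.heappush(heap, (w, start, v))
    edges: dict[Edge, float] = {}
    while heap and len(in_tree) < len(graph.labels):
        w, u, v = heapq.heappop(heap)
        if v in in_tree:
            continue
        in_tree.add(v)
        edges[_norm_edge(u, v)] = w
        for w2, x in adj[v]:
            if x not in in_tree:
                heapq.heappush(heap, (w2, v, x))
    return SpanningTree(list(graph.labels), edges)


def mst_from_distances(dm: DistanceMatrix) -> SpanningTree:
    """MST directly on the complete distance graph (all unmasked pairs)."""
    g = build_neighbor_graph(dm, float(dm.d.max()) + 1.0, None)
    return prim_mst(g)


def root_to_node(tree: SpanningTree, root: str = "G") -> dict[str, float]:
    """Cumulative path weight from the root to every node; sorting the values
    ascending induces the chronology order."""
    if root not in tree.labels:
        raise TreeError(f"unknown root {root!r}")
    adj = tree.adjacency()
    dist = {root: 0.0}
    stack = [root]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    if len(dist) != len(tree.labels):
        raise TreeError("tree is not connected")
    return dist


def chronology_order(tree: SpanningTree, root: str = "G") -> list[str]:
    """Labels sorted by ascending root-to-node distance (label-lexicographic
    on exact ties)."""
    dist = root_to_node(tree, root)
    return sorted(tree.labels, key=lambda l: (dist[l], l))


@dataclass
class ChronologyRanks:
    per_metric: pd.DataFrame   # entities x metrics, tie-grouped ranks
    composite: pd.Series       # mean rank per entity


def rank_chronology(
    table: MetricsTable | pd.DataFrame, tie_threshold: float = 0.005
) -> ChronologyRanks:
    """Ascending per-metric ranks with near-ties grouped, then averaged.

    Each column is min-max normalized before tie detection so the absolute
    threshold (default 0.005) is meaningful across metrics; values whose
    consecutive normalized gaps are <= threshold share a rank (chain rule).
    Grouped values take the mean of the ranks they span.
    """
    df = table.values if isinstance(table, MetricsTable) else table
    if df.isna().any().any():
        raise TreeError("rank chronology requires a complete metrics table")
    ranks = {}
    for col in df.columns:
        x = df[col]
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise TreeError(f"metric {col!r} is constant")
        norm = (x - lo) / (hi - lo)
        order = norm.sort_values(kind="mergesort").index
        vals = norm[order].to_numpy()
        # group consecutive values with gap <= threshold
        groups: list[list[int]] = [[0]]
        for i in range(1, len(vals)):
            if vals[i] - vals[groups[-1][-1]] <= tie_threshold:
                groups[-1].append(i)
            else:
                groups.append([i])
        col_ranks = pd.Series(index=df.index, dtype=float)
        pos = 1
        for grp in groups:
            mean_rank = pos + (len(grp) - 1) / 2
            for i in grp:
                col_ranks[order[i]] = mean_rank
            pos += len(grp)
        ranks[col] = col_ranks
    per_metric = pd.DataFrame(ranks)
    return ChronologyRanks(per_metric=per_metric, composite=per_metric.mean(axis=1))


def compare_trees(t1: SpanningTree, t2: SpanningTree) -> dict[str, float]:
    """Jaccard edge similarity and adjacency similarity
    (1 − normalized Hamming distance between adjacency matrices)."""
    if sorted(t1.labels) != sorted(t2.labels):
        raise TreeError("trees must share the same label set")
    e1, e2 = t1.edge_set(), t2.edge_set()
    union = e1 | e2
    jac = len(e1 & e2) / len(union) if union else 1.0
    n = len(t1.labels)
    n_offdiag_pairs = n * (n - 1) // 2
    hamming = len(e1 ^ e2) / n_offdiag_pairs
    return {"jaccard": jac, "adjacency_similarity": 1.0 - hamming}


# ---------------------------------------------------------------------------
# serialization

def export_edge_list(tree: SpanningTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label1\tlabel2\tweight\n")
        for (a, b), w in sorted(tree.edges.items()):
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_edge_list(path: str | Path) -> SpanningTree:
    edges: dict[Edge, float] = {}
    labels: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("label1"):
            raise TreeError("edge-list TSV must start with a label1/label2/weight header")
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            edges[_norm_edge(a, b)] = float(w)
            labels.update((a, b))
    return SpanningTree(sorted(labels), edges)


def to_newick(tree: SpanningTree, root: str) -> str:
    """Newick with branch lengths equal to edge weights, rooted at ``root``."""
    if root not in tree.labels:
        raise TreeError(f"unknown root {root!r}")
    adj = tree.adjacency()

    def render(node: str, parent: str | None) -> str:
        children = sorted((v, w) for v, w in adj[node] if v != parent)
        if not children:
            return node
        inner = ",".join(f"{render(v, node)}:{w:g}" for v, w in children)
        return f"({inner}){node}"

    return render(root, None) + ";"
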