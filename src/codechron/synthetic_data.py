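"""Seeded generators for synthetic inputs with the statistical structure the
pipeline assumes: low-rank metric tables, linearly usage-linked vectors,
path-alkane molecular graphs, and uniform random labeled trees."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from codechron.complexity_metrics import (
    Atom,
    GRAPH_FRAMEWORK,
    INFO_FRAMEWORK,
    MetricsTable,
    MolecularGraph,
)
from codechron.genetic_code import AMINO_ACIDS
from codechron.tree_inference import SpanningTree, _norm_edge


@dataclass(frozen=True)
class SyntheticSpec:
    n_entities: int = 20
    n_metrics: int = 16
    latent_rank: int = 3
    noise_sd: float = 0.1
    n_graph_metrics: int = 7
    shared_factor_weight: float = 0.0  # cross-block loading strength
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > min(self.n_entities, self.n_metrics):
            raise ValueError("latent_rank cannot exceed min(n_entities, n_metrics)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.n_graph_metrics <= self.n_metrics:
            raise ValueError("n_graph_metrics out of range")


def _entity_labels(n: int) -> list[str]:
    if n == 20:
        return list(AMINO_ACIDS)
    return [f"E{i:02d}" for i in range(n)]


def gen_metric_table(spec: SyntheticSpec) -> MetricsTable:
    """Low-rank-plus-noise metric table: values = L·Fᵀ + ε.

    Entity loadings L and metric loadings F are standard normal. The first
    ``n_graph_metrics`` columns are tagged 'graph' and load on the first half
    of the factors, the rest are tagged 'information' and load on the second
    half; ``shared_factor_weight`` adds cross-block loadings so between-block
    correlation is tunable from ~0 (disjoint factors) upward.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, r = spec.n_entities, spec.n_metrics, spec.latent_rank
    loadings = rng.standard_normal((n, r))
    fmat = rng.standard_normal((p, r))

    half = max(1, r // 2) if r > 1 else 1
    block = np.full((p, r), spec.shared_factor_weight)
    block[: spec.n_graph_metrics, :half] = 1.0
    block[spec.n_graph_metrics :, half:] = 1.0
    if r == 1:
        block[:, :] = 1.0
    fmat = fmat * block

    values = loadings @ fmat.T
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    labels = _entity_labels(n)
    cols = [f"m{i:02d}" for i in range(p)]
    frameworks = {
        c: (GRAPH_FRAMEWORK if i < spec.n_graph_metrics else INFO_FRAMEWORK)
        for i, c in enumerate(cols)
    }
    df = pd.DataFrame(values, index=labels, columns=cols)
    if n == 20:
        return MetricsTable(df, frameworks)
    # MetricsTable enforces the amino-acid row set; return a bare frame otherwise
    table = MetricsTable.__new__(MetricsTable)
    table.values = df
    table.frameworks = frameworks
    return table


def gen_usage(
    scores: dict[str, float],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """usage = intercept + slope·score + N(0, noise_sd²), per label."""
    rng = np.random.default_rng(seed)
    labels = sorted(scores)
    x = np.array([scores[l] for l in labels], dtype=float)
    usage = intercept + slope * x + rng.normal(0.0, noise_sd, size=len(labels))
    return pd.DataFrame({"usage": usage, "stderr": np.full(len(labels), noise_sd)},
                        index=pd.Index(labels, name="label"))


def gen_path_alkane(n_vertices: int) -> MolecularGraph:
    """Hydrogen-suppressed n-alkane backbone: a path of sp3 carbons, no
    chiral centers."""
    if n_vertices < 2:
        raise ValueError("alkane backbone needs at least 2 carbons")
    atoms = [Atom("C", is_sp3_carbon=True) for _ in range(n_vertices)]
    bonds = [(i, i + 1) for i in range(n_vertices - 1)]
    return MolecularGraph(atoms, bonds)


def prufer_decode(seq: list[int], n: int) -> list[tuple[int, int]]:
    """Edges of the labeled tree with Prüfer sequence ``seq`` on nodes 0..n−1."""
    if len(seq) != n - 2:
        raise ValueError("Prüfer sequence for n nodes has length n-2")
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def gen_random_tree(n_nodes: int, seed: int = 0, labels: list[str] | None = None) -> SpanningTree:
    """Uniform random labeled tree via a random Prüfer sequence, unit weights."""
    if n_nodes < 2:
        raise ValueError("a tree needs at least 2 nodes")
    if labels is None:
        labels = _entity_labels(n_nodes)
    if len(labels) != n_nodes:
        raise ValueError("label count must equal n_nodes")
    rng = np.random.default_rng(seed)
    if n_nodes == 2:
        idx_edges = [(0, 1)]
    else:
        seq = rng.integers(0, n_nodes, size=n_nodes - 2).tolist()
        idx_edges = prufer_decode(seq, n_nodes)
    edges = {_norm_edge(labels[a], labels[b]): 1.0 for a, b in idx_edges}
    return SpanningTree(sorted(labels), edges)


def tree_to_networkx(tree: SpanningTree) -> "nx.Graph":
    g = nx.Graph()
    g.add_nodes_from(tree.labels)
    for (a, b), w in tree.edges.items():
        g.add_edge(a, b, weight=w)
    return g
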