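"""ε-graphs, Prim MST against Kruskal and exhaustive oracles, chronology
extraction, ranks, and tree comparison / serialization."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from codechron.complexity_space import DistanceMatrix, autoscale, distance_matrix
from codechron.tree_inference import (
    NeighborGraph,
    SpanningTree,
    TreeError,
    build_neighbor_graph,
    chronology_order,
    compare_trees,
    export_edge_list,
    min_connectivity_eps,
    mst_from_distances,
    prim_mst,
    rank_chronology,
    read_edge_list,
    root_to_node,
    to_newick,
)


def random_dm(rng, n):
    pts = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix([f"n{i:02d}" for i in range(n)], squareform(pdist(pts)))


def graph_from_weights(labels, weights):
    edges = {}
    for (a, b), w in weights.items():
        edges[(a, b) if a <= b else (b, a)] = w
    return NeighborGraph(labels, edges, eps_per_dim=np.inf, eps_total=np.inf)


# ---------------------------------------------------------------------------
# neighbor graph

def test_eps_below_min_gives_empty_graph(rng):
    dm = random_dm(rng, 20)
    tiny = dm.condensed().min() / 2
    g = build_neighbor_graph(dm, tiny)
    assert len(g.edges) == 0
    assert g.n_components == 20


def test_eps_above_max_gives_complete_graph(rng):
    dm = random_dm(rng, 10)
    g = build_neighbor_graph(dm, dm.d.max() + 1)
    assert len(g.edges) == 45
    assert g.n_components == 1


def test_two_clusters_split_below_gap():
    pts = np.array([[0.0], [0.1], [0.2], [5.0], [5.1]])
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(list("abcde"), squareform(pdist(pts)))
    g = build_neighbor_graph(dm, 4.7)  # just below the 4.8 bridging gap
    assert g.n_components == 2


def test_eps_total_linear_in_dim(rng):
    dm = random_dm(rng, 8)
    g = build_neighbor_graph(dm, 0.5, dim=7)
    assert g.eps_total == pytest.approx(3.5)


def test_min_connectivity_eps_collinear():
    from scipy.spatial.distance import pdist, squareform

    pts = np.array([[0.0], [1.0], [5.0]])
    dm = DistanceMatrix(list("abc"), squareform(pdist(pts)))
    eps = min_connectivity_eps(dm, dim=None, grid_step=0.5)
    assert eps == pytest.approx(4.0)  # largest bridging gap


def test_min_connectivity_eps_equals_max_mst_edge(rng):
    for _ in range(5):
        dm = random_dm(rng, 12)
        tree = mst_from_distances(dm)
        max_edge = max(tree.edges.values())
        eps = min_connectivity_eps(dm, dim=None, grid_step=1e-3)
        assert max_edge <= eps <= max_edge + 1e-3


def test_grid_refinement_monotone(rng):
    dm = random_dm(rng, 10)
    coarse = min_connectivity_eps(dm, dim=None, grid_step=0.2)
    fine = min_connectivity_eps(dm, dim=None, grid_step=0.1)
    assert fine <= coarse + 1e-12


# ---------------------------------------------------------------------------
# MST

def test_prim_triangle():
    g = graph_from_weights(list("abc"), {("a", "b"): 1.0, ("b", "c"): 2.0, ("a", "c"): 3.0})
    t = prim_mst(g)
    assert sorted(t.edges.values()) == [1.0, 2.0]
    assert t.total_weight == pytest.approx(3.0)


def test_prim_on_path_graph_returns_path():
    labels = [f"n{i}" for i in range(6)]
    weights = {(labels[i], labels[i + 1]): float(i + 1) for i in range(5)}
    t = prim_mst(graph_from_weights(labels, weights))
    assert t.edge_set() == frozenset(
        (a, b) if a <= b else (b, a) for a, b in weights
    )


def test_prim_disconnected_error():
    g = NeighborGraph(list("abc"), {("a", "b"): 1.0}, 1.0, 1.0)
    with pytest.raises(TreeError, match="eps"):
        prim_mst(g)


def brute_force_mst(labels, weights):
    """Minimum over all spanning trees by exhaustive edge-subset enumeration."""
    n = len(labels)
    best, best_w = None, np.inf
    edges = list(weights.items())
    for subset in combinations(edges, n - 1):
        try:
            t = SpanningTree(labels, dict(subset))
        except TreeError:
            continue
        if t.total_weight < best_w:
            best, best_w = t, t.total_weight
    return best


def test_prim_equals_kruskal_and_exhaustive(rng):
    for trial in range(6):
        n = int(rng.integers(4, 9))
        labels = [f"n{i}" for i in range(n)]
        g_nx = nx.gnm_random_graph(n, min(n + 4, n * (n - 1) // 2), seed=int(rng.integers(1e6)))
        if not nx.is_connected(g_nx):
            g_nx = nx.complete_graph(n)
        weights = {}
        for a, b in g_nx.edges():
            la, lb = labels[a], labels[b]
            weights[(la, lb) if la <= lb else (lb, la)] = float(rng.random()) + 0.01
        graph = graph_from_weights(labels, weights)
        t_prim = prim_mst(graph)

        h = nx.Graph()
        h.add_nodes_from(labels)
        for (a, b), w in weights.items():
            h.add_edge(a, b, weight=w)
        t_kruskal = nx.minimum_spanning_tree(h, algorithm="kruskal")
        kruskal_edges = frozenset(
            (a, b) if a <= b else (b, a) for a, b in t_kruskal.edges()
        )
        assert t_prim.edge_set() == kruskal_edges

        t_brute = brute_force_mst(labels, weights)
        assert t_prim.edge_set() == t_brute.edge_set()


def test_mst_topology_invariant_under_monotone_transform(rng):
    dm = random_dm(rng, 10)
    t1 = mst_from_distances(dm)
    dm_sq = DistanceMatrix(dm.labels, dm.d**2)
    t2 = mst_from_distances(dm_sq)
    assert t1.edge_set() == t2.edge_set()


# ---------------------------------------------------------------------------
# chronology

def test_root_to_node_chain():
    t = SpanningTree(list("ABC"), {("A", "B"): 2.0, ("B", "C"): 3.0}, root="A")
    assert root_to_node(t, "A") == {"A": 0.0, "B": 2.0, "C": 5.0}


def test_root_to_node_errors():
    t = SpanningTree(list("AB"), {("A", "B"): 1.0})
    with pytest.raises(TreeError):
        root_to_node(t, "Z")


def test_chronology_order_invariant_to_rescaling(rng):
    dm = random_dm(rng, 12)
    t1 = mst_from_distances(dm)
    t2 = mst_from_distances(DistanceMatrix(dm.labels, dm.d * 7.0))
    root = dm.labels[0]
    assert chronology_order(t1, root) == chronology_order(t2, root)


# ---------------------------------------------------------------------------
# ranks

def test_rank_chronology_distinct_column(complete_table):
    df = pd.DataFrame(
        {"m": np.linspace(0, 1, 20)}, index=complete_table.values.index
    )
    ranks = rank_chronology(df, tie_threshold=0.005)
    expected = np.arange(1, 21, dtype=float)
    order = df["m"].sort_values().index
    assert np.allclose(ranks.per_metric.loc[order, "m"], expected)
    assert ranks.composite.min() >= 1 and ranks.composite.max() <= 20


def test_rank_chronology_near_tie_grouped():
    vals = np.linspace(0, 1, 6).tolist()
    vals[1] = vals[0] + 0.004 * (vals[-1] - vals[0])  # within threshold
    df = pd.DataFrame({"m": vals}, index=list("abcdef"))
    ranks = rank_chronology(df, tie_threshold=0.005)
    assert ranks.per_metric.loc["a", "m"] == ranks.per_metric.loc["b", "m"]


def test_rank_chronology_identical_columns():
    vals = np.linspace(0, 5, 8)
    df = pd.DataFrame({"m1": vals, "m2": vals}, index=list("abcdefgh"))
    ranks = rank_chronology(df)
    assert np.allclose(ranks.composite, ranks.per_metric["m1"])


# ---------------------------------------------------------------------------
# tree comparison

def test_compare_identical_trees(rng):
    from codechron.synthetic_data import gen_random_tree

    t = gen_random_tree(10, seed=4)
    res = compare_trees(t, t)
    assert res == {"jaccard": 1.0, "adjacency_similarity": 1.0}


def test_compare_edge_disjoint_trees():
    t1 = SpanningTree(list("ABCD"), {("A", "B"): 1, ("B", "C"): 1, ("C", "D"): 1})
    t2 = SpanningTree(list("ABCD"), {("A", "C"): 1, ("A", "D"): 1, ("B", "D"): 1})
    res = compare_trees(t1, t2)
    assert res["jaccard"] == 0.0
    assert res["adjacency_similarity"] == 1.0 - 6 / 6


def test_compare_trees_sharing_nine_edges():
    labels = [f"n{i:02d}" for i in range(20)]
    path_edges = {(labels[i], labels[i + 1]): 1.0 for i in range(19)}
    t1 = SpanningTree(labels, path_edges)
    shared = dict(list(path_edges.items())[:9])          # n00-n01 ... n08-n09
    star = {(labels[0], labels[k]): 1.0 for k in range(10, 20)}
    t2 = SpanningTree(labels, {**shared, **star})
    res = compare_trees(t1, t2)
    assert res["jaccard"] == pytest.approx(9 / 29)


def test_compare_label_mismatch():
    t1 = SpanningTree(list("AB"), {("A", "B"): 1})
    t2 = SpanningTree(list("AC"), {("A", "C"): 1})
    with pytest.raises(TreeError):
        compare_trees(t1, t2)


# ---------------------------------------------------------------------------
# serialization

def test_newick_single_edge():
    t = SpanningTree(list("AB"), {("A", "B"): 2.0})
    assert to_newick(t, "A") == "(B:2)A;"


def test_newick_parsable_by_dendropy(rng):
    import dendropy

    from codechron.synthetic_data import gen_random_tree

    t = gen_random_tree(8, seed=1)
    nwk = to_newick(t, t.labels[0])
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(parsed.leaf_nodes()) >= 1  # syntactically valid


def test_edge_list_roundtrip(tmp_path):
    from codechron.synthetic_data import gen_random_tree

    t = gen_random_tree(20, seed=9)
    p = tmp_path / "tree.tsv"
    export_edge_list(t, p)
    lines = p.read_text().strip().splitlines()
    assert len(lines) == 20  # header + 19 edges
    back = read_edge_list(p)
    assert back.edge_set() == t.edge_set()
    assert back.edges == t.edges
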