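"""Mutational-connectivity statistics of an amino-acid tree: observed
per-position mutation counts, permutation null with seeded reproducibility,
the path-graph closed-form null, and substitution-matrix comparison."""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from codechron.genetic_code import AMINO_ACIDS, CodonTable, DEFAULT_TABLE
from codechron.tree_inference import SpanningTree

POSITIONS = (1, 2, 3, None)  # None = all positions


def _position_key(p: int | None) -> str:
    return "all" if p is None else str(p)


@dataclass(frozen=True)
class TreeMutationSummary:
    """Per-position mutation totals over the 19 tree edges.

    ``observed_fraction`` uses the documented convention
    Σ_edges S / Σ_edges M_i with i the endpoint nearer the root (falling back
    to the lexicographically first endpoint for unrooted trees).
    """

    observed_count: dict[str, int]
    observed_fraction: dict[str, float]


def _check_tree(tree: SpanningTree, full: bool = True) -> None:
    bad = set(tree.labels) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-canonical tree labels: {sorted(bad)}")
    if full and sorted(tree.labels) != sorted(AMINO_ACIDS):
        raise ValueError("tree labels must be exactly the 20 canonical amino acids")


def tree_mutation_counts(
    tree: SpanningTree, code: CodonTable = DEFAULT_TABLE
) -> TreeMutationSummary:
    _check_tree(tree, full=False)
    # endpoint nearer the root, for the fraction denominator convention
    if tree.root is not None:
        from codechron.tree_inference import root_to_node

        depth = root_to_node(tree, tree.root)
        nearer = {e: (a if depth[a] <= depth[b] else b) for e in tree.edges for a, b in [e]}
    else:
        nearer = {e: e[0] for e in tree.edges}

    counts: dict[str, int] = {}
    fracs: dict[str, float] = {}
    for p in POSITIONS:
        s_total = sum(code.count_single_point(a, b, p) for a, b in tree.edges)
        m_total = sum(code.mutation_capacity(nearer[e], p) for e in tree.edges)
        counts[_position_key(p)] = s_total
        fracs[_position_key(p)] = s_total / m_total
    return TreeMutationSummary(observed_count=counts, observed_fraction=fracs)


@dataclass(frozen=True)
class RandomizationResult:
    n_trials: int
    seed: int
    mean: dict[str, float]
    sd: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    observed: dict[str, int] | None
    enriched: dict[str, bool] | None


def randomize_assignments(
    tree: SpanningTree,
    n_trials: int = 100_000,
    seed: int = 0,
    code: CodonTable = DEFAULT_TABLE,
    observed: TreeMutationSummary | None = None,
) -> RandomizationResult:
    """Permutation null: uniform random bijections of amino acids onto the
    fixed tree topology; per-position mutation totals over the 19 edges.

    95% CI is the printed normal form μ ± 1.96·σ/√N. The expectation is
    topology-independent: 19 × per-pair mean for every position.
    """
    _check_tree(tree)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    u = np.array([idx[a] for a, _ in tree.edges])
    v = np.array([idx[b] for _, b in tree.edges])

    cmats = {p: code.count_matrix(p) for p in (1, 2, 3)}
    rng = np.random.default_rng(seed)

    totals = {p: np.empty(n_trials, dtype=np.int64) for p in (1, 2, 3)}
    chunk = 20_000
    done = 0
    while done < n_trials:
        m = min(chunk, n_trials - done)
        perms = np.argsort(rng.random((m, 20)), axis=1)
        pu = perms[:, u]
        pv = perms[:, v]
        for p in (1, 2, 3):
            totals[p][done : done + m] = cmats[p][pu, pv].sum(axis=1)
        done += m
    totals_all = totals[1] + totals[2] + totals[3]

    mean, sd, lo, hi = {}, {}, {}, {}
    for p in POSITIONS:
        arr = totals_all if p is None else totals[p]
        key = _position_key(p)
        mu = float(arr.mean())
        sigma = float(arr.std(ddof=1)) if n_trials > 1 else 0.0
        half = float(1.96 * sigma / np.sqrt(n_trials))
        mean[key], sd[key] = mu, sigma
        lo[key], hi[key] = mu - half, mu + half

    obs = observed.observed_count if observed is not None else None
    enriched = (
        {k: bool(obs[k] > hi[k]) for k in obs} if obs is not None else None
    )
    return RandomizationResult(
        n_trials=n_trials,
        seed=seed,
        mean=mean,
        sd=sd,
        ci_low=lo,
        ci_high=hi,
        observed=obs,
        enriched=enriched,
    )


def path_graph_null(code: CodonTable = DEFAULT_TABLE) -> dict[str, float]:
    """Closed-form expected per-position mutation totals for a randomly
    labeled 20-node path graph: E(p) = 19 × per-pair mean."""
    return {
        _position_key(p): float(code.path_graph_expectation(p)) for p in POSITIONS
    }


def substitution_matrix_compare(
    tree: SpanningTree, matrix: pd.DataFrame
) -> dict[str, float]:
    """Mean substitution-matrix value over the tree edges versus over all
    unordered label pairs."""
    _check_tree(tree, full=False)
    labels = list(matrix.index)
    if sorted(labels) != sorted(tree.labels) or [str(c) for c in matrix.columns] != labels:
        raise ValueError("matrix must be square over the tree's label set")
    vals = matrix.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, equal_nan=True):
        raise ValueError("substitution matrix must be symmetric")
    m = matrix.astype(float)
    adjacent = [m.loc[a, b] for a, b in tree.edges]
    all_pairs = [
        m.loc[labels[i], labels[j]]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    return {
        "mean_adjacent": float(np.mean(adjacent)),
        "mean_all": float(np.mean(all_pairs)),
    }


def summary_table(
    observed: TreeMutationSummary, null: RandomizationResult
) -> pd.DataFrame:
    """Observed counts/fractions alongside randomized means and 95% CIs,
    mirroring the per-position connectivity summary layout."""
    rows = []
    for key, label in (("1", "first"), ("2", "second"), ("3", "third"), ("all", "total")):
        half = null.ci_high[key] - null.mean[key]
        rows.append(
            {
                "position": label,
                "observed_count": observed.observed_count[key],
                "observed_fraction": observed.observed_fraction[key],
                "randomized_mean": null.mean[key],
                "ci_half_width": half,
                "enriched": observed.observed_count[key] > null.ci_high[key],
            }
        )
    return pd.DataFrame(rows)
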