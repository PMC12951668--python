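"""Topological complexity indices on hydrogen-suppressed molecular graphs,
composite transforms, and the metrics-table reader.

Only indices fully determined by the graph plus atom annotations are computed
here (walk counts, Zagreb, Kier kappa, Balaban J, chiral/sp3 fractions, and
Euclidean-norm composites). Externally sourced index values are ingested via
:func:`load_metrics_table` and never recomputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from codechron.genetic_code import AMINO_ACIDS

GRAPH_FRAMEWORK = "graph"
INFO_FRAMEWORK = "information"


class MoleculeError(ValueError):
    """Invalid molecular graph or degenerate index request."""


class TableFormatError(ValueError):
    """Malformed metrics table."""


@dataclass(frozen=True)
class Atom:
    element: str
    is_sp3_carbon: bool = False
    is_chiral_center: bool = False


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph: annotated atoms + bonds.

    Bonds are unordered atom-index pairs; ``order`` is kept for provenance but
    the indices below treat the graph as simple and unweighted.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    orders: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n < 1:
            raise MoleculeError("molecular graph needs at least one atom")
        seen = set()
        for i, j in self.bonds:
            if i == j:
                raise MoleculeError(f"self-loop at atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise MoleculeError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MoleculeError(f"duplicate bond {key}")
            seen.add(key)
        if not self.orders:
            self.orders = [1.0] * len(self.bonds)
        if n > 1 and not self._connected():
            raise MoleculeError("molecular graph must be connected")

    def _connected(self) -> bool:
        adj = self.adjacency()
        n = len(self.atoms)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        return len(seen) == n

    def adjacency(self) -> np.ndarray:
        n = len(self.atoms)
        a = np.zeros((n, n), dtype=np.int64)
        for i, j in self.bonds:
            a[i, j] = a[j, i] = 1
        return a

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "MolecularGraph":
        """Read ``{"atoms": [{"element", "sp3"?, "chiral"?}...], "bonds": [[i,j]...]}``."""
        with open(path) as fh:
            doc = json.load(fh)
        atoms = [
            Atom(
                element=a["element"],
                is_sp3_carbon=bool(a.get("sp3", False)),
                is_chiral_center=bool(a.get("chiral", False)),
            )
            for a in doc["atoms"]
        ]
        bonds = [tuple(b[:2]) for b in doc["bonds"]]
        orders = [float(b[2]) if len(b) > 2 else 1.0 for b in doc["bonds"]]
        return cls(atoms, bonds, orders)


# ---------------------------------------------------------------------------
# walk counts

def total_walk_count(g: MolecularGraph) -> int:
    """Σ_{k=1}^{V-1} 1ᵀ A^k 1 — every walk counted from each start atom,
    with no one-half symmetry factor."""
    n = g.n_atoms
    if n < 2:
        raise MoleculeError("walk count undefined for a single-atom graph")
    a = g.adjacency()
    ones = np.ones(n, dtype=object)  # exact integer arithmetic
    vec = ones
    total = 0
    for _ in range(n - 1):
        vec = a @ vec
        total += int(vec.sum())
    return total


def log_wcx(g: MolecularGraph) -> float:
    """Base-10 log of the total walk count (base is inert after autoscaling)."""
    return math.log10(total_walk_count(g))


# ---------------------------------------------------------------------------
# classical indices

def zagreb_indices(g: MolecularGraph) -> tuple[int, int]:
    """First and second Zagreb indices: M1 = Σ deg², M2 = Σ_edges deg·deg."""
    deg = g.degrees()
    m1 = int((deg**2).sum())
    m2 = int(sum(deg[i] * deg[j] for i, j in g.bonds))
    return m1, m2


def _path_count(g: MolecularGraph, length: int) -> int:
    """Number of simple paths with ``length`` edges (unordered endpoints)."""
    adj: list[list[int]] = [[] for _ in range(g.n_atoms)]
    for i, j in g.bonds:
        adj[i].append(j)
        adj[j].append(i)

    count = 0

    def extend(path: list[int], remaining: int) -> None:
        nonlocal count
        if remaining == 0:
            count += 1
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + [nxt], remaining - 1)

    for start in range(g.n_atoms):
        extend([start], length)
    return count // 2  # each path traversed from both ends


def kappa_indices(g: MolecularGraph) -> tuple[float | None, float | None, float | None]:
    """Kier shape indices (1κ, 2κ, 3κ); degenerate orders report None."""
    a = g.n_atoms
    out: list[float | None] = []
    for order in (1, 2, 3):
        p = _path_count(g, order)
        if p == 0:
            out.append(None)
            continue
        if order == 1:
            val = a * (a - 1) ** 2 / p**2
        elif order == 2:
            val = (a - 1) * (a - 2) ** 2 / p**2
        else:
            if a % 2 == 1:
                val = (a - 1) * (a - 3) ** 2 / p**2
            else:
                val = (a - 3) * (a - 2) ** 2 / p**2
        out.append(val)
    return tuple(out)  # type: ignore[return-value]


def balaban_j(g: MolecularGraph) -> float:
    """Balaban's distance-sum connectivity index
    J = m/(μ+1) · Σ_edges (s_i s_j)^(-1/2), μ = m − n + 1."""
    from scipy.sparse.csgraph import shortest_path

    n, m = g.n_atoms, len(g.bonds)
    if n == 1:
        raise MoleculeError("Balaban J undefined for a single atom")
    dist = shortest_path(g.adjacency(), method="D", unweighted=True)
    s = dist.sum(axis=1)
    mu = m - n + 1
    acc = sum(1.0 / math.sqrt(s[i] * s[j]) for i, j in g.bonds)
    return m / (mu + 1) * acc


def fraction_indices(g: MolecularGraph) -> tuple[float, float]:
    """(FCC, FSP3): chiral-center and sp3 fractions over carbon atoms.

    Annotations are read from the atom flags; perception is out of scope.
    """
    carbons = [a for a in g.atoms if a.element.upper() == "C"]
    if not carbons:
        raise MoleculeError("fraction indices need at least one carbon")
    fcc = sum(a.is_chiral_center for a in carbons) / len(carbons)
    fsp3 = sum(a.is_sp3_carbon for a in carbons) / len(carbons)
    return fcc, fsp3


def euclidean_combine(values: Sequence[float | None]) -> float | None:
    """√(Σ v²); any missing component makes the composite missing."""
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
        return None
    return math.sqrt(sum(float(v) ** 2 for v in values))


# ---------------------------------------------------------------------------
# metrics table

@dataclass
class MetricsTable:
    """20 amino acids × named complexity metrics with framework tags.

    ``values`` is indexed by the one-letter symbols; missing cells are NaN.
    ``frameworks`` maps metric name -> 'graph' | 'information' (optional).
    """

    values: pd.DataFrame
    frameworks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = list(self.values.index)
        if sorted(idx) != sorted(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(idx)
            extra = set(idx) - set(AMINO_ACIDS)
            raise TableFormatError(
                f"row set must be the 20 amino acids; missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate metric columns: {dups}")
        unknown = {
            f for f in self.frameworks.values() if f not in (GRAPH_FRAMEWORK, INFO_FRAMEWORK)
        }
        if unknown:
            raise TableFormatError(f"unknown framework tags: {sorted(unknown)}")
        self.values = self.values.reindex(list(AMINO_ACIDS)).astype(float)

    @property
    def metrics(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def subset(self, framework: str) -> "MetricsTable":
        cols = [m for m in self.metrics if self.frameworks.get(m) == framework]
        if not cols:
            raise TableFormatError(f"no metrics tagged {framework!r}")
        return MetricsTable(self.values[cols].copy(), {c: framework for c in cols})

    def to_csv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.columns = [
            f"{c}#{self.frameworks[c]}" if c in self.frameworks else c for c in df.columns
        ]
        df.to_csv(path, index_label="aa")


def load_metrics_table(path: str | Path) -> MetricsTable:
    """Read a metrics CSV: first column = amino-acid symbol, one column per
    metric. A framework tag may be embedded in the header as ``name#graph`` /
    ``name#information``; untagged columns carry no tag.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    frameworks: dict[str, str] = {}
    names: list[str] = []
    for col in df.columns:
        name, sep, tag = str(col).partition("#")
        name = name.strip()
        if sep:
            frameworks[name] = tag.strip().lower()
        names.append(name)
    df.columns = names
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = df.index[bad][0]
            raise TableFormatError(f"non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    return MetricsTable(df, frameworks)
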