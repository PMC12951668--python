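"""Codon-level combinatorics of the standard genetic code.

Single-point mutation counts between amino acids, per-codon mutation
capacities, mutation fractions, per-pair background means, and the
closed-form expectation for a randomly labeled path graph.

Conventions
-----------
* RNA alphabet internally ({A, U, G, C}); DNA input (T) is transliterated.
* Codon positions are 1-based; ``position=None`` means all three positions.
* Substitutions to or from stop codons never count as connecting mutations,
  but capacities are defined purely from codon multiplicity (9·n or 3·n).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

RNA_BASES = ("A", "U", "G", "C")

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

STOP = "*"

#: Standard genetic code, RNA codons -> one-letter amino acid or '*' (stop).
STANDARD_CODE: dict[str, str] = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

N_PAIRS = 190  # unordered pairs of distinct amino acids: C(20, 2)

_POSITIONS = (1, 2, 3)


class AlphabetError(ValueError):
    """Unknown amino-acid symbol or malformed codon."""


def _normalize_codon(codon: str) -> str:
    codon = codon.strip().upper().replace("T", "U")
    if len(codon) != 3 or any(b not in RNA_BASES for b in codon):
        raise AlphabetError(f"malformed codon: {codon!r}")
    return codon


def _check_aa(aa: str) -> str:
    if aa == STOP:
        raise AlphabetError("STOP is not an amino acid; use CodonTable.stop_codons")
    if aa not in AMINO_ACIDS:
        raise AlphabetError(f"unknown amino-acid symbol: {aa!r}")
    return aa


def _check_position(position: int | None) -> int | None:
    if position is not None and position not in _POSITIONS:
        raise ValueError(f"codon position must be 1, 2, 3 or None, got {position!r}")
    return position


@dataclass(frozen=True)
class CodonTable:
    """A genetic code: mapping of 64 codons to amino acids / stop.

    The default instance is the standard code. Alternative codes may be
    supplied as a mapping or loaded from a two-column CSV (codon, symbol).
    """

    entries: Mapping[str, str] = field(default_factory=lambda: dict(STANDARD_CODE))

    def __post_init__(self) -> None:
        entries = {_normalize_codon(c): s.strip().upper() for c, s in self.entries.items()}
        if len(entries) != 64:
            raise ValueError(f"expected 64 codons, got {len(entries)}")
        bad = {s for s in entries.values() if s != STOP and s not in AMINO_ACIDS}
        if bad:
            raise AlphabetError(f"unknown symbols in code table: {sorted(bad)}")
        missing = set(AMINO_ACIDS) - set(entries.values())
        if missing:
            raise ValueError(f"amino acids with no codon: {sorted(missing)}")
        object.__setattr__(self, "entries", entries)
        by_aa: dict[str, frozenset[str]] = {}
        for codon, sym in entries.items():
            by_aa.setdefault(sym, set()).add(codon)  # type: ignore[arg-type]
        object.__setattr__(
            self, "_by_symbol", {s: frozenset(cs) for s, cs in by_aa.items()}
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CodonTable":
        entries: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].lstrip().startswith("#"):
                    continue
                if row[0].strip().lower() in {"codon", "codons"}:
                    continue
                if len(row) < 2:
                    raise ValueError(f"bad code-table row: {row!r}")
                entries[row[0]] = row[1]
        return cls(entries)

    # -- basic accessors ---------------------------------------------------

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c, s in self.entries.items() if s != STOP)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, s in self.entries.items() if s == STOP)

    def codons_for(self, aa: str) -> frozenset[str]:
        """Codon set of one amino acid (never the stop set)."""
        return self._by_symbol[_check_aa(aa)]  # type: ignore[attr-defined]

    def degeneracy(self, aa: str) -> int:
        """n_i: number of codons encoding ``aa``."""
        return len(self.codons_for(aa))

    def translate(self, codon: str) -> str:
        return self.entries[_normalize_codon(codon)]

    # -- single-point mutation combinatorics -------------------------------

    def count_single_point(self, ai: str, aj: str, position: int | None = None) -> int:
        """Number of codon pairs (c, c') with c -> ai, c' -> aj differing at
        exactly one nucleotide (restricted to ``position`` when given).

        Symmetric in (ai, aj). ``ai == aj`` is a domain error: synonymous
        interchanges are not amino-acid-connecting mutations here.
        """
        _check_position(position)
        if _check_aa(ai) == _check_aa(aj):
            raise ValueError("count_single_point requires two distinct amino acids")
        count = 0
        for c in self.codons_for(ai):
            for cp in self.codons_for(aj):
                diff = [p for p in range(3) if c[p] != cp[p]]
                if len(diff) != 1:
                    continue
                if position is None or diff[0] == position - 1:
                    count += 1
        return count

    def mutation_capacity(self, ai: str, position: int | None = None) -> int:
        """M_i = 9·n_i over all positions, or 3·n_i for a single position."""
        _check_position(position)
        n = self.degeneracy(ai)
        return 9 * n if position is None else 3 * n

    def mutation_fraction(self, ai: str, aj: str, position: int | None = None) -> float:
        """F_{i->j}: probability a random single-point mutation in a codon of
        ``ai`` yields ``aj``. Asymmetric (denominator is the source capacity)."""
        return self.count_single_point(ai, aj, position) / self.mutation_capacity(ai, position)

    def count_matrix(self, position: int | None = None):
        """20x20 symmetric integer matrix of count_single_point, zero diagonal.

        Row/column order follows :data:`AMINO_ACIDS`.
        """
        import numpy as np

        n = len(AMINO_ACIDS)
        m = np.zeros((n, n), dtype=np.int64)
        for i, j in combinations(range(n), 2):
            s = self.count_single_point(AMINO_ACIDS[i], AMINO_ACIDS[j], position)
            m[i, j] = m[j, i] = s
        return m

    # -- background rates --------------------------------------------------

    def background_per_pair_mean(self, position: int | None = None) -> Fraction:
        """Mean connecting-mutation count over the 190 unordered pairs.

        Exact rational; rounds to the conventional 0.44 / 0.46 / 0.13 at
        positions 1 / 2 / 3 for the standard code.
        """
        _check_position(position)
        total = sum(
            self.count_single_point(ai, aj, position)
            for ai, aj in combinations(AMINO_ACIDS, 2)
        )
        return Fraction(total, N_PAIRS)

    def background_fraction_diagnostic(self, position: int | None = None) -> float:
        """Literal per-amino-acid mean of capacity-normalized outgoing
        fractions: (1/20) Σ_k Σ_j S_{k->j}(p) / M_k(p).

        Diagnostic only — inconsistent with the per-pair mean convention used
        everywhere else in the pipeline; exposed for transparency.
        """
        _check_position(position)
        acc = 0.0
        for ak in AMINO_ACIDS:
            cap = self.mutation_capacity(ak, position)
            out = sum(
                self.count_single_point(ak, aj, position)
                for aj in AMINO_ACIDS
                if aj != ak
            )
            acc += out / cap
        return acc / len(AMINO_ACIDS)

    def path_graph_expectation(self, position: int | None = None) -> Fraction:
        """E(p) = 19 × per-pair mean: expected mutation total of a randomly
        labeled 20-node tree (topology-independent)."""
        return (len(AMINO_ACIDS) - 1) * self.background_per_pair_mean(position)


#: Module-level default instance of the standard code.
DEFAULT_TABLE = CodonTable()


def codons_for(aa: str) -> frozenset[str]:
    return DEFAULT_TABLE.codons_for(aa)


def count_single_point(ai: str, aj: str, position: int | None = None) -> int:
    return DEFAULT_TABLE.count_single_point(ai, aj, position)


def mutation_capacity(ai: str, position: int | None = None) -> int:
    return DEFAULT_TABLE.mutation_capacity(ai, position)


def mutation_fraction(ai: str, aj: str, position: int | None = None) -> float:
    return DEFAULT_TABLE.mutation_fraction(ai, aj, position)


def background_per_pair_mean(position: int | None = None) -> Fraction:
    return DEFAULT_TABLE.background_per_pair_mean(position)


def path_graph_expectation(position: int | None = None) -> Fraction:
    return DEFAULT_TABLE.path_graph_expectation(position)
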