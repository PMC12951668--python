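"""Amino-acid distance matrices in metric space: autoscaling, Euclidean
distances with missing-pair masking, min-max normalization, and matrix
comparison statistics (Pearson, Spearman, two-sample KS)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from codechron.complexity_metrics import MetricsTable


class SpaceError(ValueError):
    pass


def autoscale(table: MetricsTable | pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x − mean)/sd with sample (n−1) sd; NaN cells stay NaN.

    Constant columns are an error (zero variance has no scale). Accepts a
    :class:`MetricsTable` or a bare labeled DataFrame.
    """
    df = table.values if isinstance(table, MetricsTable) else table
    scaled = {}
    for col in df.columns:
        x = df[col]
        sd = x.std(ddof=1)  # pandas skips NaN
        if not np.isfinite(sd) or sd == 0:
            raise SpaceError(f"metric {col!r} is constant (or has <2 values); cannot autoscale")
        scaled[col] = (x - x.mean()) / sd
    return pd.DataFrame(scaled, index=df.index)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over labeled entities.

    ``mask`` marks unusable (missing) pairs; the diagonal is always zero and
    never masked.
    """

    labels: list[str]
    d: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise SpaceError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if self.mask is None:
            self.mask = np.zeros((n, n), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        np.fill_diagonal(self.mask, False)
        valid = ~self.mask
        if not np.allclose(self.d[valid], self.d.T[valid], equal_nan=True):
            raise SpaceError("distance matrix is not symmetric")
        if np.nanmin(np.where(self.mask, np.inf, self.d)) < -1e-12:
            raise SpaceError("negative distances")
        if not np.allclose(np.diag(self.d), 0.0):
            raise SpaceError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_pairs(self) -> list[tuple[int, int]]:
        n = self.n
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def condensed(self, include_masked: bool = False) -> np.ndarray:
        """Upper-triangle vector; masked entries become NaN unless included."""
        out = []
        for i, j in self.upper_pairs():
            if self.mask[i, j] and not include_masked:
                out.append(np.nan)
            else:
                out.append(self.d[i, j])
        return np.array(out)

    def n_masked_pairs(self) -> int:
        return sum(self.mask[i, j] for i, j in self.upper_pairs())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(np.where(self.mask, np.nan, self.d),
                          index=self.labels, columns=self.labels)
        df.to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.index]
        if [str(c) for c in df.columns] != labels:
            raise SpaceError("distance CSV must be square with matching labels")
        d = df.to_numpy(dtype=float)
        mask = np.isnan(d)
        d = np.nan_to_num(d, nan=0.0)
        return cls(labels, d, mask)


def distance_matrix(scaled: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances over columns complete for both rows.

    A pair with no shared complete column is masked. With a complete input
    this is the plain Euclidean distance matrix.
    """
    labels = list(scaled.index)
    x = scaled.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(np.isnan(x[i]) | np.isnan(x[j]))
            if not shared.any():
                mask[i, j] = mask[j, i] = True
                continue
            diff = x[i, shared] - x[j, shared]
            d[i, j] = d[j, i] = float(np.sqrt((diff**2).sum()))
    return DistanceMatrix(labels, d, mask)


def normalize_distances(dm: DistanceMatrix) -> DistanceMatrix:
    """Min-max map of all unmasked off-diagonal entries onto [0, 1]."""
    vals = dm.condensed()
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise SpaceError("need at least two unmasked pairs")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise SpaceError("all distances equal; min-max normalization undefined")
    d = (dm.d - lo) / (hi - lo)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(dm.labels, d, dm.mask.copy())


@dataclass(frozen=True)
class MatrixComparison:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    ks_D: float
    ks_p: float
    n_pairs_used: int
    n_pairs_excluded: int


def compare_matrices(d1: DistanceMatrix, d2: DistanceMatrix) -> MatrixComparison:
    """Pearson/Spearman over upper triangles restricted to pairs unmasked in
    both matrices; two-sample KS between the two usable distance populations."""
    if d1.labels != d2.labels:
        raise SpaceError("matrices must share the same label set and order")
    v1 = d1.condensed()
    v2 = d2.condensed()
    usable = ~(np.isnan(v1) | np.isnan(v2))
    n_used = int(usable.sum())
    if n_used < 3:
        raise SpaceError(f"only {n_used} usable pairs; need at least 3")
    r, rp = stats.pearsonr(v1[usable], v2[usable])
    rho, sp = stats.spearmanr(v1[usable], v2[usable])
    ks = stats.ks_2samp(v1[usable], v2[usable])
    return MatrixComparison(
        pearson_r=float(r),
        pearson_p=float(rp),
        spearman_rho=float(rho),
        spearman_p=float(sp),
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        n_pairs_used=n_used,
        n_pairs_excluded=len(v1) - n_used,
    )
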