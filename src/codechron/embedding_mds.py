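"""Classical (Torgerson) metric MDS with rank truncation, reconstruction-error
reporting, and minimal-dimension search.

Negative eigenvalues of the double-centered Gram matrix (non-Euclidean noise)
are clipped to zero, never used for coordinates; they are surfaced in the
diagnostics so callers can judge how non-Euclidean the input is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from codechron.complexity_space import DistanceMatrix


@dataclass
class Embedding:
    labels: list[str]
    coords: np.ndarray            # n x d
    eigenvalues: np.ndarray       # all n, descending
    mean_rel_error: float
    p95_rel_error: float

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def distances(self) -> DistanceMatrix:
        d = squareform(pdist(self.coords))
        return DistanceMatrix(self.labels, d)


def _gram_from_distances(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def classical_mds(dm: DistanceMatrix, dim: int) -> Embedding:
    """Double-center −½·J·D²·J, keep the top ``dim`` nonnegative eigenpairs,
    scale eigenvectors by √λ.

    Canonicalized output: eigenvalues descending; each axis signed so its
    largest-magnitude coordinate is positive. If fewer than ``dim`` positive
    eigenvalues exist the effective dimension is reduced with a warning.
    """
    if dm.mask.any():
        raise ValueError("classical MDS requires a complete distance matrix")
    n = dm.n
    if not 1 <= dim <= n - 1:
        raise ValueError(f"dim must be in [1, {n - 1}], got {dim}")
    b = _gram_from_distances(dm.d)
    evals, evecs = np.linalg.eigh(b)          # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    pos = evals > max(evals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    eff = min(dim, n_pos)
    if eff < dim:
        warnings.warn(
            f"requested dim {dim} exceeds {n_pos} positive eigenvalues; using {eff}",
            RuntimeWarning,
        )
    lam = np.clip(evals[:eff], 0.0, None)
    coords = evecs[:, :eff] * np.sqrt(lam)

    # sign canonicalization: largest-|coordinate| entry positive per axis
    for k in range(coords.shape[1]):
        col = coords[:, k]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            coords[:, k] = -col

    mean_rel, p95_rel = reconstruction_error(dm, coords)
    return Embedding(
        labels=list(dm.labels),
        coords=coords,
        eigenvalues=evals,
        mean_rel_error=mean_rel,
        p95_rel_error=p95_rel,
    )


def reconstruction_error(dm: DistanceMatrix, coords: np.ndarray) -> tuple[float, float]:
    """Relative error |d̂ − d|/d over unordered pairs with d > 0.

    Returns (mean, 95th percentile by linear interpolation). Zero original
    distances are skipped with a warning.
    """
    dhat = squareform(pdist(coords))
    errs = []
    skipped = 0
    for i, j in dm.upper_pairs():
        if dm.mask[i, j]:
            continue
        if dm.d[i, j] <= 0:
            skipped += 1
            continue
        errs.append(abs(dhat[i, j] - dm.d[i, j]) / dm.d[i, j])
    if skipped:
        warnings.warn(f"skipped {skipped} zero-distance pairs", RuntimeWarning)
    if not errs:
        raise ValueError("no usable pairs for reconstruction error")
    arr = np.array(errs)
    return float(arr.mean()), float(np.percentile(arr, 95, method="linear"))


def min_dimension(dm: DistanceMatrix, mean_error_threshold: float = 0.02) -> int:
    """Smallest dimension whose mean relative reconstruction error is below
    the threshold; returns n−1 with a warning if never reached."""
    n = dm.n
    for dim in range(1, n):
        emb = classical_mds(dm, dim)
        if emb.mean_rel_error < mean_error_threshold:
            return dim
    warnings.warn(
        f"mean error threshold {mean_error_threshold} not reached below dim {n - 1}",
        RuntimeWarning,
    )
    return n - 1
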