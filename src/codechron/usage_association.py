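"""Association of chronology scores with amino-acid usage vectors and with
molecular weight."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from codechron.genetic_code import AMINO_ACIDS
from codechron.complexity_metrics import MetricsTable

#: Free amino-acid molecular weights (g/mol), average isotopic composition.
MOLECULAR_WEIGHTS: dict[str, float] = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "V": 117.15, "W": 204.23, "Y": 181.19,
}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def ols_fit(x, y) -> RegressionResult:
    """Unweighted ordinary least squares; two-sided p for the slope (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    if np.ptp(y) == 0:
        # flat response: zero slope explains nothing, and there is no evidence
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, 0.0, len(x))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(x),
    )


def load_usage_table(path: str | Path) -> pd.DataFrame:
    """Usage CSV with columns label, usage[, stderr]; validates the 20 labels."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "label" not in df.columns or "usage" not in df.columns:
        raise ValueError("usage CSV needs 'label' and 'usage' columns")
    df["label"] = df["label"].astype(str).str.strip().str.upper()
    df = df.set_index("label")
    if sorted(df.index) != sorted(AMINO_ACIDS):
        raise ValueError("usage table must cover exactly the 20 amino acids")
    return df


def usage_regression(scores: dict[str, float], usage: pd.DataFrame) -> RegressionResult:
    """OLS of usage on a chronology score (root-to-node distance or composite
    rank), aligned on amino-acid labels."""
    labels = list(AMINO_ACIDS)
    x = [scores[l] for l in labels]
    y = [float(usage.loc[l, "usage"]) for l in labels]
    return ols_fit(x, y)


def weight_complexity_r2(
    table: MetricsTable, weights: dict[str, float] | None = None
) -> float:
    """Squared Pearson correlation of the pooled per-metric min-max-normalized
    values (20 × p points) against molecular weight.

    Constant metrics are excluded with a warning.
    """
    import warnings

    if weights is None:
        weights = MOLECULAR_WEIGHTS
    df = table.values
    if df.isna().any().any():
        raise ValueError("weight correlation requires a complete table")
    xs, ys = [], []
    w = np.array([weights[l] for l in df.index])
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"metric {col!r} is constant; excluded", RuntimeWarning)
            continue
        norm = (v - v.min()) / (v.max() - v.min())
        xs.append(np.broadcast_to(w, norm.shape).copy())
        ys.append(norm)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    r, _ = stats.pearsonr(x, y)
    return float(r**2)
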