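"""Dual Shannon-entropy diversity of TE expression.

Two entropies (natural log) per cell population over TE subfamilies:

* per-cell entropy — each cell's abundance vector is ln(1 + raw count) per
  subfamily, renormalized to proportions; the population is summarized by
  the median across its cells;
* population entropy — each cell contributes a binary expressed/not vector
  (raw count > 0); column sums give per-subfamily expression frequencies
  whose proportions define the entropy.

Regressing population entropy (y) on median per-cell entropy (x) by ordinary
least squares gives a per-population deviation delta_y = y - y_hat: large
positive values indicate a mosaic repertoire (broad at the population level
but narrow per cell, the mTEC pattern), values near zero a homogeneous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversityPoint",
    "diversity_points",
    "fit_diversity_model",
    "per_cell_entropy",
    "population_entropy",
    "shannon_entropy",
]


@dataclass(frozen=True)
class DiversityPoint:
    population: str
    median_cell_entropy: float
    population_entropy: float
    predicted: float = float("nan")
    delta_y: float = float("nan")


def shannon_entropy(abundances) -> float:
    """Shannon entropy (nats) of a non-negative abundance vector; the vector
    is renormalized to proportions and an all-zero vector has entropy 0."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        return 0.0
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def _subfamily_counts(adata, population: str, population_key: str):
    from .sc_core import _counts

    mask = (adata.obs[population_key] == population).to_numpy()
    if not mask.any():
        raise ValueError(f"population {population!r} has no cells")
    sub_mask = (adata.var["kind"] == "te_subfamily").to_numpy()
    if not sub_mask.any():
        raise ValueError("no te_subfamily features; aggregate first")
    return _counts(adata)[np.flatnonzero(mask), :][:, sub_mask].toarray()


def per_cell_entropy(adata, population: str, population_key: str = "cell_type") -> tuple[np.ndarray, float]:
    """Per-cell Shannon entropy of ln(1 + count) subfamily abundances and the
    population median."""
    C = _subfamily_counts(adata, population, population_key)
    A = np.log1p(C)
    H = np.array([shannon_entropy(row) for row in A])
    return H, float(np.median(H))


def population_entropy(adata, population: str, population_key: str = "cell_type") -> float:
    """Shannon entropy of per-subfamily expression frequencies (number of
    cells with count > 0) within the population."""
    C = _subfamily_counts(adata, population, population_key)
    freq = (C > 0).sum(axis=0).astype(float)
    if freq.sum() == 0:
        warnings.warn(f"population {population!r} expresses no subfamily; entropy 0")
        return 0.0
    return shannon_entropy(freq)


def diversity_points(
    adata, populations=None, population_key: str = "cell_type", postnatal_only: bool = False
) -> pd.DataFrame:
    """x = median per-cell entropy and y = population entropy per population."""
    data = adata
    if postnatal_only:
        data = adata[(adata.obs["era"] == "postnatal").to_numpy()]
    if populations is None:
        populations = list(pd.unique(data.obs[population_key]))
    rows = []
    for pop in populations:
        _, med = per_cell_entropy(data, pop, population_key)
        rows.append(
            {"population": pop, "median_cell_entropy": med,
             "population_entropy": population_entropy(data, pop, population_key)}
        )
    return pd.DataFrame(rows).set_index("population")


def fit_diversity_model(points: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """OLS of population entropy on median per-cell entropy.

    Adds ``predicted`` and ``delta_y`` (= observed - predicted; residuals sum
    to 0) columns. Returns (augmented frame, slope, intercept).
    """
    if len(points) < 3:
        raise ValueError("need >= 3 populations")
    x = points["median_cell_entropy"].to_numpy(dtype=float)
    y = points["population_entropy"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("median per-cell entropy is constant; fit undefined")
    slope, intercept = np.polyfit(x, y, deg=1)
    out = points.copy()
    out["predicted"] = slope * x + intercept
    out["delta_y"] = y - out["predicted"]
    return out, float(slope), float(intercept)
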