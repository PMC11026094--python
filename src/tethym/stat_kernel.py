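"""Statistical primitives shared by every analysis stage.

Thin, domain-checked wrappers around scipy.stats and statsmodels: rank
correlations on mid-ranks, two-sided exact/asymptotic tests, and
multiple-testing adjustment. All tests are two-sided unless an operation
states otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PValueVector",
    "adjust_pvalues",
    "chi_squared_gof",
    "fisher_exact_2x2",
    "kendall_tau",
    "ks_two_sample",
    "spearman_rho",
    "wilcoxon_rank_sum",
]

AdjustMethod = Literal["benjamini_hochberg", "bonferroni"]


@dataclass(frozen=True)
class PValueVector:
    """Raw p-values together with their multiplicity-adjusted counterparts.

    ``adjusted[i] >= raw[i]`` and ``adjusted[i] <= 1`` always hold; the order
    of entries matches the input order.
    """

    raw: np.ndarray
    adjusted: np.ndarray
    method: AdjustMethod

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "adjusted", np.asarray(self.adjusted, dtype=float))


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks with the t-approximation p-value.

    Raises ``ValueError`` when either vector is constant (the correlation is
    undefined) or when fewer than 3 paired observations are supplied.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) with its two-sided p-value."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    tau, p = stats.kendalltau(x, y)
    return float(tau), float(p)


def adjust_pvalues(raw, method: AdjustMethod = "benjamini_hochberg") -> PValueVector:
    """Adjust a vector of p-values for multiple comparisons.

    ``benjamini_hochberg`` applies the step-up FDR procedure; ``bonferroni``
    is ``min(m * p, 1)``. Output order matches input order.
    """
    raw = _as_1d(raw, "raw")
    if raw.size == 0:
        return PValueVector(raw=raw, adjusted=raw.copy(), method=method)
    if np.any(raw < 0) or np.any(raw > 1) or np.any(np.isnan(raw)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}[method]
    adjusted = multipletests(raw, method=sm_method)[1]
    return PValueVector(raw=raw, adjusted=adjusted, method=method)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    The two-sided p-value sums hypergeometric probabilities of all tables
    (with the observed margins) no more probable than the observed one.
    """
    tbl = np.asarray(table)
    if tbl.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tbl < 0) or np.any(tbl != np.floor(tbl)):
        raise ValueError("counts must be non-negative integers")
    odds, p = stats.fisher_exact(tbl.astype(int), alternative="two-sided")
    return float(odds), float(p)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    Returns the supremum distance between the two empirical CDFs and its
    asymptotic two-sided p-value.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi_squared_gof(observed, expected_proportions) -> tuple[float, float]:
    """Pearson chi-squared goodness-of-fit test with df = k - 1."""
    obs = _as_1d(observed, "observed")
    props = _as_1d(expected_proportions, "expected_proportions")
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions must match in length")
    if obs.size < 2:
        raise ValueError("need at least 2 categories (df = k - 1 >= 1)")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed counts must sum to a positive total")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    expected = props * total
    if np.any(expected <= 0):
        raise ValueError("expected count of zero in some cell")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), float(p)


def spearman_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman correlations between two matrices sharing rows.

    Vectorized variant of :func:`spearman_rho` for screening: mid-ranks per
    column, Pearson on the ranks, p-values from the large-sample t
    approximation. Constant columns yield nan (undefined correlation).

    Returns (rho, p) of shape (x.shape[1], y.shape[1]).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x and y must be 2-d with equal row counts")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y, axis=0)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx**2).sum(axis=0))
    sy = np.sqrt((ry**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx.T @ ry) / np.outer(sx, sy)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return rho, p


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U), normal approximation
    with tie correction and no continuity correction.

    A fully tied comparison (zero rank variance) returns p = 1.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    u, p = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    if np.isnan(p):  # degenerate tie structure
        p = 1.0
    return float(u), float(p)
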