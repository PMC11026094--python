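"""Developmental expression patterns of TE subfamilies.

Per (cell type, subfamily), the mean expression across developmental stages
is max-normalized into a temporal profile. Profiles are clustered
(Euclidean distance, complete-linkage agglomerative clustering) and the tree
is cut into k=3 clusters matching the three archetypes: early expression
that persists, a single-stage spike, and early expression that decays.
Class enrichment per cluster uses Fisher exact tests; the sharing statistic
(the maximum number of cell types assigning one subfamily the same cluster)
is compared per TE class against a randomized uniform-cluster null with
Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import stat_kernel as sk
from ._rng import rng_for

__all__ = [
    "build_profiles",
    "class_enrichment",
    "cluster_profiles",
    "compare_sharing_by_class",
    "multinomial_max_pmf",
    "random_sharing_null",
    "sharing_statistic",
]


def build_profiles(adata, stage_order=None, group_by: str = "cell_type") -> pd.DataFrame:
    """Max-normalized per-stage mean lognorm expression per
    (cell type, subfamily).

    Returns a frame indexed by (cell_type, subfamily) with one column per
    stage, values in [0, 1] with max 1; all-zero profiles are excluded (they
    are reported in ``.attrs["excluded"]``).
    """
    from .sc_core import _lognorm

    stages = list(stage_order) if stage_order is not None else list(
        pd.unique(adata.obs["stage"])
    )
    if len(stages) < 2:
        raise ValueError("need >= 2 developmental stages")
    sub_mask = (adata.var["kind"] == "te_subfamily").to_numpy()
    if not sub_mask.any():
        raise ValueError("no te_subfamily features; aggregate first")
    subs = adata.var_names[sub_mask]
    L = _lognorm(adata)[:, sub_mask].toarray()

    frames = {}
    for (ct, stage), idx in adata.obs.groupby([group_by, "stage"], observed=True).groups.items():
        sel = adata.obs_names.get_indexer(idx)
        frames[(ct, stage)] = L[sel].mean(axis=0)

    rows, index = [], []
    for ct in pd.unique(adata.obs[group_by]):
        mat = np.column_stack([frames.get((ct, s), np.zeros(len(subs))) for s in stages])
        for j, sub in enumerate(subs):
            rows.append(mat[j])
            index.append((ct, sub))
    prof = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["cell_type", "subfamily"]),
        columns=stages,
    )
    maxes = prof.max(axis=1)
    excluded = prof.index[maxes == 0]
    prof = prof.loc[maxes > 0].div(maxes[maxes > 0], axis=0)
    prof.attrs["excluded"] = list(excluded)
    return prof


def cluster_profiles(profiles: pd.DataFrame, k: int = 3) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering (Euclidean, complete linkage) of normalized
    profiles, cut into exactly k clusters.

    Cluster ids are relabeled canonically by descending mean first-stage
    value so that archetypes map stably across runs. Returns (assignment
    Series indexed like ``profiles``, scipy linkage matrix).
    """
    if len(profiles) < k:
        raise ValueError(f"need >= {k} profiles")
    X = profiles.to_numpy()
    if k == 1:
        return pd.Series(1, index=profiles.index, name="cluster"), np.empty((0, 4))
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # canonical relabeling: cluster with highest mean first-stage value -> 1
    first = pd.Series(X[:, 0]).groupby(raw).mean()
    order = first.sort_values(ascending=False).index
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=profiles.index, name="cluster")
    return labels, Z


def class_enrichment(assignment: pd.Series, class_map: dict[str, str]) -> pd.DataFrame:
    """Fisher 2x2 enrichment of each TE class in each cluster over all
    assigned (cell type, subfamily) pairs, BH-adjusted over all tests."""
    if assignment.empty:
        raise ValueError("empty assignment")
    sub = assignment.index.get_level_values("subfamily")
    cls = pd.Series([class_map[s] for s in sub], index=assignment.index)
    rows = []
    for cluster in sorted(assignment.unique()):
        in_c = assignment == cluster
        for te_class in sorted(cls.unique()):
            in_k = cls == te_class
            table = [
                [int((in_c & in_k).sum()), int((in_c & ~in_k).sum())],
                [int((~in_c & in_k).sum()), int((~in_c & ~in_k).sum())],
            ]
            odds, p = sk.fisher_exact_2x2(table)
            rows.append({"cluster": cluster, "te_class": te_class, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    df["adj_p"] = sk.adjust_pvalues(df["p"].to_numpy(), method="benjamini_hochberg").adjusted
    return df


def sharing_statistic(assignment: pd.Series) -> pd.Series:
    """Per subfamily, the maximal number of cell types assigned the same
    cluster (over cell types where the subfamily was assigned at all)."""
    ct = assignment.index.get_level_values("cell_type")
    if pd.unique(ct).size < 2:
        raise ValueError("sharing requires >= 2 cell types")
    df = assignment.rename("cluster").reset_index()
    counts = df.groupby(["subfamily", "cluster"], observed=True).size()
    return counts.groupby(level="subfamily").max().rename("sharing")


def random_sharing_null(
    n_subfamilies: int, n_cell_types: int, k: int = 3, seed: int = 0
) -> np.ndarray:
    """Null sample of the sharing statistic: each (subfamily, cell type)
    independently receives a uniform cluster in {1..k}."""
    if min(n_subfamilies, n_cell_types, k) <= 0:
        raise ValueError("dimensions must be positive")
    rng = rng_for(seed, "sharing_null")
    draws = rng.integers(0, k, size=(n_subfamilies, n_cell_types))
    counts = np.stack([(draws == c).sum(axis=1) for c in range(k)], axis=1)
    return counts.max(axis=1)


def multinomial_max_pmf(n: int, k: int) -> np.ndarray:
    """Exact pmf of the maximum cell of Multinomial(n, 1/k), indexed by
    value 0..n; the independent oracle for the randomized sharing null."""
    from math import comb

    pmf = np.zeros(n + 1)

    def rec(remaining: int, cells: int, cap: int, ways: float) -> float:
        # number of ways (multinomial coefficients summed) to place
        # `remaining` into `cells` cells each <= cap
        if cells == 0:
            return ways if remaining == 0 else 0.0
        total = 0.0
        for x in range(min(cap, remaining) + 1):
            total += rec(remaining - x, cells - 1, cap, ways * comb(remaining, x))
        return total

    denom = float(k) ** n
    prev = 0.0
    for cap in range(0, n + 1):
        cum = rec(n, k, cap, 1.0) / denom
        pmf[cap] = cum - prev
        prev = cum
    return pmf


def compare_sharing_by_class(
    observed_by_class: dict[str, np.ndarray], null_sample: np.ndarray
) -> pd.DataFrame:
    """Two-sample KS of each class's sharing-statistic sample against the
    randomized null sample."""
    rows = []
    for te_class, sample in observed_by_class.items():
        sample = np.asarray(sample, dtype=float)
        if sample.size == 0:
            raise ValueError(f"empty sample for class {te_class!r}")
        d, p = sk.ks_two_sample(sample, np.asarray(null_sample, dtype=float))
        rows.append({"te_class": te_class, "D": d, "p": p, "n": sample.size})
    return pd.DataFrame(rows)
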