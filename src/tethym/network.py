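"""TF-TE interaction inference.

Within one cell population, every (transcription factor, TE subfamily) pair
is screened by Spearman correlation on log-normalized expression with BH
correction; a candidate passes when rho >= 0.2, adjusted p <= 0.05 and the
TF has positive raw counts in >= 10% of the population's cells. Candidates
are validated by a with-replacement bootstrap (default 1000 iterations)
whose empirical p-value is the fraction of resamples with rho below the
screen threshold. An interaction additionally requires that at least one
locus of the subfamily harbors the TF's binding motif; the displayed subset
of the network uses the stricter rho >= 0.3 and motif support in >= 1% of
loci. TE loci of interacting subfamilies that carry the motif are classified
as promoter or enhancer candidates from H3K27ac/H3K4me1/H3K4me3 peak
colocalization and TSS distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import stat_kernel as sk
from ._rng import derive_seed
from .intervals import PeakSet, TEAnnotation, distance_to_nearest_tss, intersect_any

__all__ = [
    "InteractionNetwork",
    "bootstrap_validate",
    "build_network",
    "classify_te_locus",
    "correlation_screen",
    "genome_space_association",
    "motif_support",
]


def correlation_screen(
    adata,
    tf_list,
    population: str,
    rho_cut: float = 0.2,
    alpha: float = 0.05,
    min_expr_fraction: float = 0.10,
    population_key: str = "cell_type",
    min_cells: int = 30,
) -> pd.DataFrame:
    """Spearman screen of every (TF, subfamily) pair within one population.

    BH is applied over all pairs tested in the population. The returned
    frame has one row per pair with rho, p, adj_p, tf_expr_fraction and the
    boolean ``passed`` (rho >= rho_cut, adj_p <= alpha, TF expressed in >=
    min_expr_fraction of cells). Absent TFs are skipped with a warning.
    """
    from .sc_core import _counts, _lognorm

    mask = (adata.obs[population_key] == population).to_numpy()
    if mask.sum() < min_cells:
        raise ValueError(f"population {population!r} has < {min_cells} cells")
    sub = adata[mask]

    tf_list = list(dict.fromkeys(tf_list))
    present = [t for t in tf_list if t in set(sub.var_names)]
    absent = set(tf_list) - set(present)
    if absent:
        warnings.warn(f"{len(absent)} TFs absent from registry; skipped")
    if not present:
        raise ValueError("no TF from the list present in the registry")

    sub_mask = (sub.var["kind"] == "te_subfamily").to_numpy()
    subs = sub.var_names[sub_mask]
    L = _lognorm(sub)
    tf_idx = sub.var_names.get_indexer(present)
    X_tf = L[:, tf_idx].toarray()
    X_te = L[:, sub_mask].toarray()
    C_tf = _counts(sub)[:, tf_idx]
    expr_frac = np.asarray((C_tf > 0).mean(axis=0)).ravel()

    rho, p = sk.spearman_matrix(X_tf, X_te)
    rows = []
    for i, tf in enumerate(present):
        for j, s in enumerate(subs):
            rows.append(
                {"population": population, "tf": tf, "subfamily": s,
                 "rho": rho[i, j], "p": p[i, j], "tf_expr_fraction": expr_frac[i]}
            )
    df = pd.DataFrame(rows)
    ok = df["rho"].notna().to_numpy()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok] = sk.adjust_pvalues(df.loc[ok, "p"].to_numpy(), "benjamini_hochberg").adjusted
    df["adj_p"] = adj
    df["passed"] = (
        ok
        & (df["rho"] >= rho_cut)
        & (df["adj_p"] <= alpha)
        & (df["tf_expr_fraction"] >= min_expr_fraction)
    )
    return df


def bootstrap_validate(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int = 1000,
    rho_threshold: float = 0.2,
    seed: int = 0,
    pair_id: tuple | None = None,
) -> float:
    """Empirical bootstrap p-value of a correlation's reproducibility.

    Cells are resampled with replacement (same n) n_iter times; the
    empirical p is the fraction of resamples whose Spearman rho falls below
    ``rho_threshold``. A resample with a constant vector counts as below
    threshold (conservative). ``pair_id`` derives a per-pair substream from
    the base seed so results are independent of execution order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sub_seed = derive_seed(seed, "bootstrap", *(pair_id or ()))
    rng = np.random.default_rng(sub_seed)
    idx = rng.integers(0, n, size=(n_iter, n))
    xr = x[idx]
    yr = y[idx]
    const = (np.ptp(xr, axis=1) == 0) | (np.ptp(yr, axis=1) == 0)
    rx = stats.rankdata(xr, axis=1)
    ry = stats.rankdata(yr, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry).sum(axis=1) / denom
    below = const | (rho < rho_threshold)
    return float(below.sum()) / n_iter


def bootstrap_validate_pairs(
    adata,
    pairs: pd.DataFrame,
    population_key: str = "cell_type",
    n_iter: int = 1000,
    rho_threshold: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`bootstrap_validate` for every row of a screen table."""
    from .sc_core import _lognorm

    out = pairs.copy()
    emp = np.empty(len(pairs))
    for pop, grp in pairs.groupby("population"):
        mask = (adata.obs[population_key] == pop).to_numpy()
        sub = adata[mask]
        L = _lognorm(sub)
        for i, row in grp.iterrows():
            x = L[:, sub.var_names.get_loc(row["tf"])].toarray().ravel()
            y = L[:, sub.var_names.get_loc(row["subfamily"])].toarray().ravel()
            emp[pairs.index.get_loc(i)] = bootstrap_validate(
                x, y, n_iter=n_iter, rho_threshold=rho_threshold, seed=seed,
                pair_id=(pop, row["tf"], row["subfamily"]),
            )
    out["empirical_p"] = emp
    return out


def motif_support(annotation: TEAnnotation, motif_occurrences: PeakSet, subfamily: str) -> float:
    """Fraction of the subfamily's loci overlapping >= 1 motif occurrence."""
    loci = annotation.subfamily_loci(subfamily)
    if len(loci) == 0:
        raise ValueError(f"subfamily {subfamily!r} has no loci")
    hits = intersect_any(loci, motif_occurrences)
    return float(hits.mean())


@dataclass
class InteractionNetwork:
    """TF-TE edges per population; ``display`` flags the stricter subset."""

    edges: pd.DataFrame  # columns: population, tf, subfamily, rho, adj_p, empirical_p, motif_fraction, display
    graph: nx.Graph = field(default_factory=nx.Graph)

    def edge_counts(self) -> pd.Series:
        return self.edges.groupby("population").size()

    def shared_pairs(self) -> pd.Series:
        """Number of populations sharing each (tf, subfamily) interaction."""
        return self.edges.groupby(["tf", "subfamily"]).size()


def build_network(
    pairs: pd.DataFrame,
    annotation: TEAnnotation,
    motifs: dict[str, PeakSet],
    display_rho: float = 0.3,
    display_motif_fraction: float = 0.01,
) -> InteractionNetwork:
    """Assemble the interaction network from validated screen pairs.

    An edge requires a screen pass and motif support in > 0 of the
    subfamily's loci; a display edge additionally requires rho >=
    ``display_rho`` and motif support in >= ``display_motif_fraction`` of
    loci.
    """
    df = pairs[pairs["passed"]].copy()
    fracs = []
    for row in df.itertuples(index=False):
        ps = motifs.get(row.tf)
        fracs.append(motif_support(annotation, ps, row.subfamily) if ps is not None and len(ps) else 0.0)
    df["motif_fraction"] = fracs
    df = df[df["motif_fraction"] > 0].reset_index(drop=True)
    df["display"] = (df["rho"] >= display_rho) & (df["motif_fraction"] >= display_motif_fraction)

    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.tf, kind="tf")
        g.add_node(row.subfamily, kind="te_subfamily")
        g.add_edge(
            row.tf, row.subfamily, population=row.population, rho=row.rho,
            adj_p=row.adj_p, motif_fraction=row.motif_fraction,
        )
    return InteractionNetwork(edges=df, graph=g)


def genome_space_association(network: InteractionNetwork, annotation: TEAnnotation) -> dict:
    """Does genomic occupancy track regulatory connectivity?

    Per subfamily: the number of TF interactions (over all populations) and
    the number of annotated loci; Kendall tau between the two, plus pairwise
    rank-sum comparisons of interaction counts between TE classes.
    """
    n_loci = annotation.loci.groupby("subfamily").size()
    n_inter = network.edges.groupby("subfamily").size()
    table = pd.DataFrame({"n_loci": n_loci}).fillna(0)
    table["n_interactions"] = n_inter.reindex(table.index).fillna(0).astype(int)
    if len(table) < 3:
        raise ValueError("need >= 3 subfamilies")
    tau, p = sk.kendall_tau(table["n_interactions"].to_numpy(), table["n_loci"].to_numpy())

    cls = annotation.subfamily_class_map()
    table["te_class"] = [cls[s] for s in table.index]
    comparisons = []
    classes = sorted(table["te_class"].unique())
    if len(classes) < 2:
        warnings.warn("single TE class; class comparisons skipped")
    else:
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                xa = table.loc[table["te_class"] == a, "n_interactions"].to_numpy()
                xb = table.loc[table["te_class"] == b, "n_interactions"].to_numpy()
                _, pp = sk.wilcoxon_rank_sum(xa, xb)
                comparisons.append({"class_a": a, "class_b": b, "p": pp})
    return {"table": table, "tau": tau, "tau_p": p, "class_comparisons": pd.DataFrame(comparisons)}


def classify_te_locus(
    locus,
    marks: dict[str, PeakSet],
    tss: PeakSet,
    tss_max_dist: int = 1000,
) -> str:
    """Promoter/enhancer/neither call for one TE locus.

    Enhancer: overlaps H3K27ac and H3K4me1 but not H3K4me3. Promoter:
    overlaps H3K27ac and H3K4me3 but not H3K4me1 and lies within
    ``tss_max_dist`` of a TSS. The calls are mutually exclusive by
    construction.
    """
    required = {"H3K27ac", "H3K4me1", "H3K4me3"}
    if not required.issubset(marks):
        raise ValueError(f"missing mark sets: {sorted(required - set(marks))}")
    from .intervals import TELocus

    if isinstance(locus, TELocus):
        iv = locus.interval
        frame = pd.DataFrame({"chrom": [iv.chrom], "start": [iv.start], "end": [iv.end]})
    else:
        frame = pd.DataFrame(
            {"chrom": [locus["chrom"]], "start": [locus["start"]], "end": [locus["end"]]}
        )
    ac = bool(intersect_any(frame, marks["H3K27ac"])[0])
    me1 = bool(intersect_any(frame, marks["H3K4me1"])[0])
    me3 = bool(intersect_any(frame, marks["H3K4me3"])[0])
    if ac and me1 and not me3:
        return "enhancer"
    if ac and me3 and not me1:
        if distance_to_nearest_tss(PeakSet.from_frame("q", frame), tss)[0] <= tss_max_dist:
            return "promoter"
    return "neither"


def classify_loci(
    loci: pd.DataFrame, marks: dict[str, PeakSet], tss: PeakSet, tss_max_dist: int = 1000
) -> pd.Series:
    """Vectorized promoter/enhancer/neither calls for a locus frame."""
    required = {"H3K27ac", "H3K4me1", "H3K4me3"}
    if not required.issubset(marks):
        raise ValueError(f"missing mark sets: {sorted(required - set(marks))}")
    ac = intersect_any(loci, marks["H3K27ac"])
    me1 = intersect_any(loci, marks["H3K4me1"])
    me3 = intersect_any(loci, marks["H3K4me3"])
    near = distance_to_nearest_tss(loci, tss) <= tss_max_dist
    call = np.full(len(loci), "neither", dtype=object)
    call[ac & me1 & ~me3] = "enhancer"
    call[ac & me3 & ~me1 & near] = "promoter"
    index = loci["locus_id"] if "locus_id" in loci.columns else loci.index
    return pd.Series(call, index=index, name="regulatory_call")
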