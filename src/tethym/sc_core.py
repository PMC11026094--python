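"""Single-cell matrix stage.

The in-memory container is an :class:`anndata.AnnData`: raw counts in ``X``,
log-normalized values in ``layers["lognorm"]``, per-cell metadata
(``cell_type``, ``stage``, ``era``) in ``obs``, and a feature registry in
``var`` whose ``kind`` column distinguishes genes, mitochondrial genes, TE
loci, and aggregated TE subfamilies.

Stages: QC filtering with the study's thresholds, library-size
log-normalization, locus-to-subfamily aggregation, per-group expression
summaries, expression-bin-matched module scores, score-vs-TE Spearman
screens (the same machinery serves proliferation scores and KZFP expression
vectors), and two-group rank-sum differential expression on subfamilies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from . import stat_kernel as sk
from ._rng import rng_for
from .intervals import TEAnnotation

__all__ = [
    "QCThresholds",
    "aggregate_subfamilies",
    "de_one_vs_rest",
    "expression_summary",
    "module_score",
    "normalize_lognorm",
    "qc_filter_cells",
    "read_mtx_dataset",
    "score_te_correlation_screen",
    "transcriptome_fractions",
    "two_group_de_subfamilies",
]

GENE_KINDS = ("gene", "mito_gene")
BASE_KINDS = ("gene", "mito_gene", "te_locus")  # raw (non-aggregated) features


@dataclass(frozen=True)
class QCThresholds:
    """Cell quality-control cutoffs: minimum UMI and genes detected, maximum
    mitochondrial read fraction, and the genes-detected ceiling above which a
    cell is called a doublet."""

    min_umi: int = 2000
    min_genes: int = 500
    max_mito_fraction: float = 0.05
    doublet_gene_count: int = 7000

    def __post_init__(self) -> None:
        if min(self.min_umi, self.min_genes, self.doublet_gene_count) <= 0:
            raise ValueError("count thresholds must be positive")
        if not 0 < self.max_mito_fraction < 1:
            raise ValueError("max_mito_fraction must be in (0, 1)")


def _counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)


def qc_filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()
) -> tuple[ad.AnnData, pd.Series]:
    """Remove low-quality cells and doublets.

    Rules, applied on gene-kind features (genes + mitochondrial genes) with
    the mitochondrial fraction taken over all features: UMI < min_umi,
    genes detected < min_genes, mito fraction > max_mito_fraction, and genes
    detected > doublet_gene_count. Each removed cell is labeled with the
    first matching reason in that fixed order.

    Returns (filtered dataset, per-cell removal reason for removed cells).
    """
    X = _counts(adata)
    kind = adata.var["kind"].to_numpy()
    gene_mask = np.isin(kind, GENE_KINDS)
    mito_mask = kind == "mito_gene"

    Xg = X[:, gene_mask]
    umi = np.asarray(Xg.sum(axis=1)).ravel()
    genes_detected = Xg.getnnz(axis=1)
    total = np.asarray(X.sum(axis=1)).ravel()
    if mito_mask.any():
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito / total, 0.0)
    else:
        warnings.warn("no mitochondrial genes in the registry; mito rule skipped")
        mito_frac = np.zeros(adata.n_obs)

    reasons = np.full(adata.n_obs, "", dtype=object)
    rules = [
        ("low_umi", umi < thresholds.min_umi),
        ("low_genes", genes_detected < thresholds.min_genes),
        ("high_mito", mito_frac > thresholds.max_mito_fraction),
        ("doublet", genes_detected > thresholds.doublet_gene_count),
    ]
    for name, mask in rules:
        take = mask & (reasons == "")
        reasons[take] = name

    keep = reasons == ""
    removed = pd.Series(reasons[~keep], index=adata.obs_names[~keep], name="removal_reason")
    return adata[keep].copy(), removed


def normalize_lognorm(adata: ad.AnnData) -> ad.AnnData:
    """Library-size log-normalization.

    Size factor = cell library size / median library size; the normalized
    layer is ln(1 + count / size_factor). Size factors are stored in
    ``obs["size_factor"]``. Raises on zero-library cells (QC removes them).
    """
    X = _counts(adata)
    lib = np.asarray(X.sum(axis=1)).ravel()
    if np.any(lib <= 0):
        raise ValueError("zero-library cell encountered; run QC first")
    sf = lib / np.median(lib)
    out = adata.copy()
    out.obs["size_factor"] = sf
    norm = X.multiply(1.0 / sf[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.layers["lognorm"] = norm
    return out


def aggregate_subfamilies(adata: ad.AnnData, annotation: TEAnnotation) -> ad.AnnData:
    """Append TE-subfamily features whose counts are the per-cell sums of
    their member loci.

    Every te_locus feature must be present in the annotation. Total TE
    counts are conserved exactly. When a lognorm layer exists, subfamily
    lognorm values are recomputed from the aggregated counts with the stored
    size factors.
    """
    kind = adata.var["kind"].to_numpy()
    locus_mask = kind == "te_locus"
    locus_ids = adata.var_names[locus_mask]
    known = set(annotation.loci["locus_id"])
    offenders = [l for l in locus_ids if l not in known]
    if offenders:
        raise ValueError(f"te_locus features absent from annotation: {offenders[:5]}")

    sub_of = annotation.loci.set_index("locus_id")["subfamily"]
    cls_of = annotation.subfamily_class_map()
    subs = sorted(sub_of.loc[locus_ids].unique())
    sub_idx = {s: i for i, s in enumerate(subs)}

    # loci x subfamilies indicator
    rows = np.arange(locus_mask.sum())
    cols = np.array([sub_idx[s] for s in sub_of.loc[locus_ids]])
    M = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(locus_mask.sum(), len(subs))
    )
    X = _counts(adata)
    sub_counts = (X[:, locus_mask] @ M).tocsr()

    new_var = pd.DataFrame(
        {
            "kind": "te_subfamily",
            "subfamily": subs,
            "te_class": [cls_of[s] for s in subs],
        },
        index=subs,
    )
    sub_ad = ad.AnnData(X=sub_counts, obs=adata.obs.copy(), var=new_var)
    if "lognorm" in adata.layers:
        sf = adata.obs["size_factor"].to_numpy()
        norm = sub_counts.multiply(1.0 / sf[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
        sub_ad.layers["lognorm"] = norm
        out = ad.concat([adata, sub_ad], axis=1, merge="first")
    else:
        out = ad.concat([adata, sub_ad], axis=1, merge="first")
    out.obs = adata.obs.copy()
    out.uns = dict(adata.uns)
    return out


def _lognorm(adata: ad.AnnData) -> sparse.csr_matrix:
    if "lognorm" not in adata.layers:
        raise ValueError("lognorm layer missing; run normalize_lognorm first")
    L = adata.layers["lognorm"]
    return L.tocsr() if sparse.issparse(L) else sparse.csr_matrix(L)


def expression_summary(adata: ad.AnnData, group_by: str = "cell_type") -> pd.DataFrame:
    """Per (group, subfamily): mean lognorm expression and the fraction of
    cells with a positive raw count."""
    sub_mask = (adata.var["kind"] == "te_subfamily").to_numpy()
    if not sub_mask.any():
        raise ValueError("no te_subfamily features; run aggregate_subfamilies first")
    L = _lognorm(adata)[:, sub_mask]
    C = _counts(adata)[:, sub_mask]
    subs = adata.var_names[sub_mask]

    rows = []
    for group, idx in adata.obs.groupby(group_by, observed=True).groups.items():
        sel = adata.obs_names.get_indexer(idx)
        if len(sel) == 0:
            warnings.warn(f"empty group {group!r} excluded")
            continue
        mean_ln = np.asarray(L[sel].mean(axis=0)).ravel()
        frac = np.asarray((C[sel] > 0).mean(axis=0)).ravel()
        for s, m, fr in zip(subs, mean_ln, frac):
            rows.append({"group": group, "subfamily": s, "mean_lognorm": m, "fraction_expressing": fr})
    return pd.DataFrame(rows)


def transcriptome_fractions(adata: ad.AnnData, group_by: str = "cell_type") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cell, the fraction of raw counts on TE loci and on mitochondrial
    genes (denominator: all gene/mito/locus counts, excluding aggregated
    subfamily features to avoid double counting); plus per-group quantiles.
    """
    X = _counts(adata)
    kind = adata.var["kind"].to_numpy()
    base = np.isin(kind, BASE_KINDS)
    total = np.asarray(X[:, base].sum(axis=1)).ravel()
    te = np.asarray(X[:, kind == "te_locus"].sum(axis=1)).ravel()
    mito = np.asarray(X[:, kind == "mito_gene"].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cell = pd.DataFrame(
            {
                "group": adata.obs[group_by].to_numpy(),
                "te_fraction": np.where(total > 0, te / total, 0.0),
                "mito_fraction": np.where(total > 0, mito / total, 0.0),
            },
            index=adata.obs_names,
        )
    qs = [0.25, 0.5, 0.75]
    summary = (
        per_cell.groupby("group", observed=True)[["te_fraction", "mito_fraction"]]
        .quantile(qs)
        .unstack()
    )
    return per_cell, summary


def module_score(
    adata: ad.AnnData,
    program_genes,
    n_bins: int = 25,
    n_ctrl_per_gene: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell score of a gene program against expression-matched controls.

    Gene-kind features are binned into ``n_bins`` by their dataset-wide mean
    lognorm expression; for each program gene, up to ``n_ctrl_per_gene``
    control genes are sampled (seeded, without replacement) from its bin.
    Score = mean(program lognorm) - mean(control lognorm) per cell.
    """
    kind = adata.var["kind"].to_numpy()
    gene_mask = np.isin(kind, GENE_KINDS)
    genes = adata.var_names[gene_mask]
    L = _lognorm(adata)[:, gene_mask]

    program = sorted(set(program_genes))
    present = [g for g in program if g in set(genes)]
    dropped = set(program) - set(present)
    if dropped:
        warnings.warn(f"{len(dropped)} program genes absent from registry; dropped")
    if not present:
        raise ValueError("no program gene present in the registry")

    mean_expr = pd.Series(np.asarray(L.mean(axis=0)).ravel(), index=genes)
    # quantile bins on ranked mean expression (ties broken by rank)
    order = mean_expr.rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)

    rng = rng_for(seed, "module_score")
    gene_pos = {g: i for i, g in enumerate(genes)}
    control: set[str] = set()
    for g in present:
        pool = bins.index[(bins == bins[g]) & (bins.index != g)].tolist()
        k = min(n_ctrl_per_gene, len(pool))
        if k:
            control.update(rng.choice(np.array(sorted(pool)), size=k, replace=False).tolist())
    control -= set(present)
    if not control:
        control = set(present)  # degenerate bin: controls equal the program

    prog_idx = [gene_pos[g] for g in present]
    ctrl_idx = [gene_pos[g] for g in sorted(control)]
    score = (
        np.asarray(L[:, prog_idx].mean(axis=1)).ravel()
        - np.asarray(L[:, ctrl_idx].mean(axis=1)).ravel()
    )
    return pd.Series(score, index=adata.obs_names, name="module_score")


def score_te_correlation_screen(
    scores: pd.Series,
    adata: ad.AnnData,
    subfamilies=None,
    rho_cut: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen of a per-cell score against TE-subfamily expression.

    BH correction is applied across the full subfamily vector; calls are
    positive (rho >= rho_cut and adj_p <= alpha), negative (rho <= -rho_cut
    and adj_p <= alpha), or none. Constant subfamilies are reported with
    rho = nan and call none. The same machinery serves the KZFP screen with
    a KZFP expression vector as the score.
    """
    if adata.n_obs < 3:
        raise ValueError("need >= 3 cells")
    scores = scores.loc[adata.obs_names]
    sub_mask = (adata.var["kind"] == "te_subfamily").to_numpy()
    subs = adata.var_names[sub_mask]
    if subfamilies is not None:
        keep = subs.isin(list(subfamilies))
        subs = subs[keep]
        L = _lognorm(adata)[:, sub_mask].toarray()[:, keep]
    else:
        L = _lognorm(adata)[:, sub_mask].toarray()

    rho, p = sk.spearman_matrix(scores.to_numpy()[:, None], L)
    rho, p = rho.ravel(), p.ravel()
    ok = ~np.isnan(rho)
    adj = np.full(len(rho), np.nan)
    if ok.any():
        adj[ok] = sk.adjust_pvalues(p[ok], method="benjamini_hochberg").adjusted
    call = np.full(len(rho), "none", dtype=object)
    call[ok & (rho >= rho_cut) & (adj <= alpha)] = "positive"
    call[ok & (rho <= -rho_cut) & (adj <= alpha)] = "negative"
    return pd.DataFrame({"rho": rho, "p": p, "adj_p": adj, "call": call}, index=subs)


def two_group_de_subfamilies(
    adata: ad.AnnData,
    group_a,
    group_b,
    alpha: float = 0.05,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Rank-sum differential expression of TE subfamilies between two cell
    groups, with log2 fold change of mean lognorm (pseudocount 1e-9) and BH
    adjustment across subfamilies."""
    a_idx = adata.obs_names.get_indexer(group_a)
    b_idx = adata.obs_names.get_indexer(group_b)
    if (a_idx < 0).any() or (b_idx < 0).any():
        raise ValueError("unknown cell ids in group definitions")
    if len(a_idx) < min_cells or len(b_idx) < min_cells:
        raise ValueError(f"both groups need >= {min_cells} cells")
    sub_mask = (adata.var["kind"] == "te_subfamily").to_numpy()
    subs = adata.var_names[sub_mask]
    L = _lognorm(adata)[:, sub_mask].toarray()

    pseudo = 1e-9
    mean_a = L[a_idx].mean(axis=0)
    mean_b = L[b_idx].mean(axis=0)
    log2fc = np.log2(mean_a + pseudo) - np.log2(mean_b + pseudo)

    pvals = np.empty(len(subs))
    for j in range(len(subs)):
        _, pvals[j] = sk.wilcoxon_rank_sum(L[a_idx, j], L[b_idx, j])
    adj = sk.adjust_pvalues(pvals, method="benjamini_hochberg").adjusted
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "adj_p": adj, "significant": adj <= alpha},
        index=subs,
    )


def de_one_vs_rest(adata: ad.AnnData, group_by: str = "cell_type", **kwargs) -> pd.DataFrame:
    """Iterate two-group DE over every group versus all remaining cells."""
    frames = []
    for group in adata.obs[group_by].unique():
        in_g = adata.obs_names[adata.obs[group_by] == group]
        out_g = adata.obs_names[adata.obs[group_by] != group]
        df = two_group_de_subfamilies(adata, in_g, out_g, **kwargs)
        df["group"] = group
        frames.append(df)
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# I/O: MatrixMarket + TSV sidecars
# ---------------------------------------------------------------------------

def read_mtx_dataset(mtx_path, barcodes_path, features_path, cell_meta_path=None) -> ad.AnnData:
    """Read a feature-barcode dataset: MTX (features x cells, MatrixMarket),
    barcodes TSV, and a features TSV with columns name/kind[/subfamily/
    te_class]; optional per-cell metadata TSV indexed by barcode."""
    from scipy.io import mmread

    M = sparse.csr_matrix(mmread(mtx_path)).T  # cells x features
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    feats = pd.read_csv(features_path, sep="\t")
    if "kind" not in feats.columns or "name" not in feats.columns:
        raise ValueError("features TSV requires 'name' and 'kind' columns")
    var = feats.set_index("name")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    if cell_meta_path is not None:
        meta = pd.read_csv(cell_meta_path, sep="\t", index_col=0)
        obs = obs.join(meta)
    return ad.AnnData(X=M, obs=obs, var=var)


def write_mtx_dataset(adata: ad.AnnData, out_dir) -> None:
    """Write counts as MatrixMarket (features x cells) with TSV sidecars."""
    from pathlib import Path

    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", _counts(adata).T.tocoo())
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    feats = adata.var.reset_index().rename(columns={"index": "name"})
    feats.to_csv(out / "features.tsv", sep="\t", index=False)
    adata.obs.to_csv(out / "cell_meta.tsv", sep="\t")
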