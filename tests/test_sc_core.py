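"""QC, normalization, aggregation, summaries, scores and DE."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from tethym import sc_core as sc
from tethym.sc_core import QCThresholds
from tethym.synthetic import SimulationConfig, simulate_single_cell_dataset, simulate_te_annotation


def make_adata(counts, kinds, obs=None, var_names=None):
    counts = np.asarray(counts)
    var = pd.DataFrame(
        {"kind": kinds, "subfamily": "", "te_class": ""},
        index=var_names or [f"f{i}" for i in range(counts.shape[1])],
    )
    obs = obs if obs is not None else pd.DataFrame(
        index=[f"c{i}" for i in range(counts.shape[0])]
    )
    return ad.AnnData(X=sparse.csr_matrix(counts.astype(float)), obs=obs, var=var)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def test_qc_hand_examples():
    # 6 gene features + 1 mito; thresholds scaled down for a readable example
    th = QCThresholds(min_umi=10, min_genes=3, max_mito_fraction=0.05, doublet_gene_count=5)
    counts = np.array(
        [
            [3, 3, 3, 3, 3, 3, 0],   # fine: UMI 18, 6 genes, no mito -> but 6 > doublet 5
            [2, 2, 2, 0, 0, 0, 0],   # low UMI (6 < 10)
            [12, 0, 0, 0, 0, 0, 0],  # 1 gene detected < 3
            [5, 5, 5, 0, 0, 0, 1],   # mito 1/16 = 0.0625 > 0.05
            [4, 4, 4, 0, 0, 0, 0],   # clean: UMI 12, 3 genes, 0 mito
        ]
    )
    adata = make_adata(counts, ["gene"] * 6 + ["mito_gene"])
    kept, removed = sc.qc_filter_cells(adata, th)
    assert removed.to_dict() == {
        "c0": "doublet", "c1": "low_umi", "c2": "low_genes", "c3": "high_mito",
    }
    assert list(kept.obs_names) == ["c4"]


def test_qc_first_matching_reason_order():
    th = QCThresholds(min_umi=10, min_genes=3, max_mito_fraction=0.05, doublet_gene_count=50)
    # violates both low_umi and high_mito -> labeled low_umi
    counts = np.array([[1, 1, 1, 5]])
    adata = make_adata(counts, ["gene"] * 3 + ["mito_gene"])
    _, removed = sc.qc_filter_cells(adata, th)
    assert removed.iloc[0] == "low_umi"


def test_qc_planted_violations_recovered():
    ann, _ = simulate_te_annotation(SimulationConfig(seed=2))
    cfg = SimulationConfig(
        seed=2, n_genes=7500, n_cells_per_group=15, qc_violation_fraction=0.03
    )
    adata = simulate_single_cell_dataset(cfg, ann)
    truth = adata.uns["truth"]["qc_reasons"]
    assert set(truth.values()) == {"low_umi", "low_genes", "high_mito", "doublet"}
    _, removed = sc.qc_filter_cells(adata)
    for cell, reason in truth.items():
        assert removed.get(cell) == reason, (cell, reason, removed.get(cell))


def test_qc_no_mito_warns_and_skips_rule():
    counts = np.array([[100] * 6])
    adata = make_adata(counts, ["gene"] * 6)
    with pytest.warns(UserWarning, match="mito"):
        kept, removed = sc.qc_filter_cells(
            adata, QCThresholds(min_umi=10, min_genes=3, doublet_gene_count=50)
        )
    assert kept.n_obs == 1 and removed.empty


def test_qc_threshold_validation():
    with pytest.raises(ValueError):
        QCThresholds(min_umi=0)
    with pytest.raises(ValueError):
        QCThresholds(max_mito_fraction=1.5)


# ---------------------------------------------------------------------------
# normalization and aggregation
# ---------------------------------------------------------------------------


def test_normalize_lognorm_formula():
    counts = np.array([[10, 0, 30], [5, 5, 10], [2, 2, 2]])
    adata = make_adata(counts, ["gene"] * 3)
    out = sc.normalize_lognorm(adata)
    lib = counts.sum(axis=1)
    sf = lib / np.median(lib)
    expected = np.log1p(counts / sf[:, None])
    assert np.allclose(out.layers["lognorm"].toarray(), expected)
    assert np.allclose(out.obs["size_factor"], sf)


def test_normalize_rejects_zero_library():
    adata = make_adata(np.array([[0, 0], [1, 2]]), ["gene", "gene"])
    with pytest.raises(ValueError, match="zero-library"):
        sc.normalize_lognorm(adata)


def test_aggregation_conserves_counts_exactly(sc_dataset, annotation):
    ann, _ = annotation
    adata = sc_dataset
    X = adata.X.toarray()
    locus_mask = (adata.var["kind"] == "te_locus").to_numpy()
    sub_mask = (adata.var["kind"] == "te_subfamily").to_numpy()
    # exact integer conservation in total and per subfamily
    assert X[:, locus_mask].sum() == X[:, sub_mask].sum()
    sub_of = ann.loci.set_index("locus_id")["subfamily"]
    for sub in ["L1syn-1", "RLTRsyn-5", "B1syn-6"]:
        member = adata.var_names.isin(
            sub_of.index[sub_of == sub]
        )
        j = adata.var_names.get_loc(sub)
        assert np.array_equal(X[:, member].sum(axis=1), X[:, j])


def test_aggregation_lognorm_uses_stored_size_factors(sc_dataset):
    adata = sc_dataset
    sub_mask = (adata.var["kind"] == "te_subfamily").to_numpy()
    sf = adata.obs["size_factor"].to_numpy()
    expected = np.log1p(adata.X.toarray()[:, sub_mask] / sf[:, None])
    assert np.allclose(adata.layers["lognorm"].toarray()[:, sub_mask], expected)


def test_aggregation_rejects_unknown_loci(annotation):
    ann, _ = annotation
    adata = make_adata(
        np.array([[1, 2]]), ["gene", "te_locus"], var_names=["g1", "mystery_locus"]
    )
    with pytest.raises(ValueError, match="absent from annotation"):
        sc.aggregate_subfamilies(adata, ann)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_expression_summary_matches_loop_oracle(sc_dataset):
    adata = sc_dataset
    df = sc.expression_summary(adata).set_index(["group", "subfamily"])
    L = adata.layers["lognorm"].toarray()
    C = adata.X.toarray()
    for group in ["mTEC", "DC"]:
        mask = (adata.obs["cell_type"] == group).to_numpy()
        for sub in ["L1syn-2", "B1syn-3"]:
            j = adata.var_names.get_loc(sub)
            row = df.loc[(group, sub)]
            assert row["mean_lognorm"] == pytest.approx(L[mask, j].mean())
            assert row["fraction_expressing"] == pytest.approx((C[mask, j] > 0).mean())


def test_transcriptome_fractions_exclude_aggregates(sc_dataset):
    adata = sc_dataset
    per_cell, summary = sc.transcriptome_fractions(adata)
    kind = adata.var["kind"].to_numpy()
    X = adata.X.toarray()
    base = np.isin(kind, ("gene", "mito_gene", "te_locus"))
    te = X[:, kind == "te_locus"].sum(axis=1)
    expected = te / X[:, base].sum(axis=1)
    assert np.allclose(per_cell["te_fraction"], expected)
    assert per_cell["te_fraction"].between(0, 1).all()
    assert (0.5, "te_fraction") not in summary.index  # summary indexed by group


# ---------------------------------------------------------------------------
# module score and screens
# ---------------------------------------------------------------------------


def test_module_score_zero_when_program_spans_registry():
    rng = np.random.default_rng(0)
    counts = rng.poisson(5.0, size=(30, 20))
    adata = sc.normalize_lognorm(make_adata(counts, ["gene"] * 20))
    # a single bin per gene set degenerates controls to the program itself
    score = sc.module_score(adata, list(adata.var_names), n_bins=1)
    assert np.allclose(score, 0.0)


def test_module_score_detects_planted_program():
    rng = np.random.default_rng(1)
    n_cells, n_genes = 100, 200
    counts = rng.poisson(5.0, size=(n_cells, n_genes))
    active = np.arange(50)  # first 50 cells up-regulate the program
    program = [f"f{j}" for j in range(10)]
    counts[np.ix_(active, np.arange(10))] += 12
    adata = sc.normalize_lognorm(make_adata(counts, ["gene"] * n_genes))
    score = sc.module_score(adata, program, seed=0)
    # separation: essentially every active cell scores above every inactive one
    thresh = np.median(score)
    assert (score[:50] > thresh).mean() > 0.9
    assert (score[50:] < thresh).mean() > 0.9


def test_module_score_determinism_and_missing_genes(sc_dataset):
    with pytest.warns(UserWarning, match="absent"):
        s1 = sc.module_score(sc_dataset, ["gene0001", "gene0002", "nope"], seed=3)
    s2 = sc.module_score(sc_dataset, ["gene0001", "gene0002"], seed=3)
    assert np.array_equal(s1.to_numpy(), s2.to_numpy())
    with pytest.raises(ValueError):
        sc.module_score(sc_dataset, ["nope"])


def test_score_screen_calls():
    rng = np.random.default_rng(2)
    n = 200
    te = rng.poisson(3.0, size=(n, 3)).astype(float)
    te[:, 2] = 1.0  # constant subfamily
    adata = make_adata(te, ["te_subfamily"] * 3, var_names=["s1", "s2", "s3"])
    adata.layers["lognorm"] = sparse.csr_matrix(te)
    up = pd.Series(te[:, 0] + rng.normal(0, 0.1, n), index=adata.obs_names)
    res = sc.score_te_correlation_screen(up, adata)
    assert res.loc["s1", "call"] == "positive"
    assert res.loc["s3", "call"] == "none" and np.isnan(res.loc["s3", "rho"])
    down = pd.Series(-te[:, 1] + rng.normal(0, 0.1, n), index=adata.obs_names)
    res2 = sc.score_te_correlation_screen(down, adata)
    assert res2.loc["s2", "call"] == "negative"
    # an unreachable rho cut produces no calls
    res3 = sc.score_te_correlation_screen(up, adata, rho_cut=1.1)
    assert (res3["call"] == "none").all()


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def _de_adata(shift):
    rng = np.random.default_rng(4)
    a = rng.poisson(2.0, size=(40, 2)).astype(float)
    b = rng.poisson(2.0, size=(40, 2)).astype(float)
    b[:, 0] += shift
    counts = np.vstack([a, b])
    adata = make_adata(counts, ["te_subfamily"] * 2, var_names=["s1", "s2"])
    adata.layers["lognorm"] = sparse.csr_matrix(np.log1p(counts))
    return adata


def test_de_direction_and_significance():
    adata = _de_adata(shift=10)
    group_a = adata.obs_names[:40]
    group_b = adata.obs_names[40:]
    res = sc.two_group_de_subfamilies(adata, group_b, group_a)
    assert res.loc["s1", "log2fc"] > 0 and res.loc["s1", "significant"]
    assert not res.loc["s2", "significant"]


def test_de_identical_groups_not_significant():
    adata = _de_adata(shift=0)
    rng = np.random.default_rng(5)
    names = rng.permutation(adata.obs_names.to_numpy())
    res = sc.two_group_de_subfamilies(adata, names[:40], names[40:])
    assert not res["significant"].any()
    assert np.abs(res["log2fc"]).max() < 0.5


def test_de_minimum_cells_enforced():
    adata = _de_adata(shift=0)
    with pytest.raises(ValueError, match=">= 10"):
        sc.two_group_de_subfamilies(adata, adata.obs_names[:5], adata.obs_names[5:])
    with pytest.raises(ValueError, match="unknown cell ids"):
        sc.two_group_de_subfamilies(adata, ["ghost"] * 10, adata.obs_names[:10])


def test_de_one_vs_rest_covers_all_groups(sc_dataset):
    res = sc.de_one_vs_rest(sc_dataset)
    assert set(res["group"]) == set(sc_dataset.obs["cell_type"].unique())
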