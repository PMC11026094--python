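"""Synthetic fixtures with planted, recoverable structure.

Every input the pipeline consumes can be generated here: sparse
negative-binomial single-cell counts with cell-type/stage structure and
latent-factor-driven TF-TE co-expression, a RepeatMasker-style TE
annotation, motif/histone/TSS/gene-model interval fixtures with known
classification outcomes, and WT/KO bulk tables with planted fold changes.
Truth labels are emitted for every planted structure so downstream recovery
tests consume only those labels.

Counts are gamma-Poisson (negative binomial) with log-normal library-size
factors. TF-TE co-expression is induced by a shared per-cell Gaussian factor
added on the log-mean scale; the factor loading is calibrated empirically so
the population Spearman correlation of log-normalized values approximates
the requested effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from ._rng import derive_seed, rng_for
from .intervals import PeakSet, TEAnnotation
from .ko import BulkExperiment

__all__ = [
    "RegulatoryFixtures",
    "SimulationConfig",
    "simulate_ko_experiment",
    "simulate_regulatory_fixtures",
    "simulate_single_cell_dataset",
    "simulate_te_annotation",
]

ARCHETYPES = ("early_persist", "stage_spike", "early_decay")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions
    the pipeline is exercised under."""

    seed: int = 0
    cell_types: tuple[str, ...] = ("mTEC", "cTEC", "DC", "Tconv")
    stages: tuple[str, ...] = ("e9pcw", "e14pcw", "p6m", "p10y")
    embryonic_stages: tuple[str, ...] = ("e9pcw", "e14pcw")
    n_cells_per_group: int = 40  # per (cell type, stage)
    n_genes: int = 1000
    n_mito_genes: int = 10
    n_te_subfamilies: Mapping[str, int] = field(
        default_factory=lambda: {"LINE": 8, "LTR": 12, "SINE": 6}
    )
    loci_per_subfamily: int = 10
    nb_dispersion: float = 0.3  # NB: var = mu + dispersion * mu^2
    library_sd: float = 0.25  # log-normal library-size factor sd
    planted_tf_te_pairs: tuple[tuple[str, str, float], ...] = ()
    temporal_archetypes: Mapping[str, str] | None = None  # None: round-robin over all
    archetype_fraction: float = 1.0
    spike_stage: int | None = None  # None: middle stage; shared by all spiking subfamilies
    planted_ko_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    low_expression_fraction: float = 0.05  # loci forced below the TPM filter
    mito_fraction_range: tuple[float, float] = (0.01, 0.03)
    qc_violation_fraction: float = 0.0  # per rule
    # annotation geometry
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    te_length_range: tuple[int, int] = (300, 3000)
    young_millidiv_mean: float = 20.0
    old_millidiv_mean: float = 200.0
    millidiv_sd: float = 5.0
    young_subfamily_fraction: float = 0.5
    clustered_n_loci: int = 0
    clustered_window: int = 100_000
    motif_fraction: float = 0.3
    # KO experiment
    ko_replicates: int = 3
    ko_base_log_mean: float = np.log(150.0)
    ko_dispersion: float = 0.04  # bulk-level biological dispersion

    def __post_init__(self) -> None:
        if self.n_cells_per_group <= 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be positive")
        if self.loci_per_subfamily <= 0 or not self.n_te_subfamilies:
            raise ValueError("TE dimensions must be positive")
        for _, _, eff in self.planted_tf_te_pairs:
            if not np.isfinite(eff):
                raise ValueError("planted effect sizes must be finite")
        if not 0 <= self.archetype_fraction <= 1:
            raise ValueError("archetype_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# TE annotation
# ---------------------------------------------------------------------------

_SUBFAMILY_STEM = {"LINE": "L1syn", "LTR": "RLTRsyn", "SINE": "B1syn"}


def subfamily_names(config: SimulationConfig) -> list[str]:
    names: list[str] = []
    for te_class in ("LINE", "LTR", "SINE"):
        n = config.n_te_subfamilies.get(te_class, 0)
        names += [f"{_SUBFAMILY_STEM[te_class]}-{i + 1}" for i in range(n)]
    return names


def _subfamily_class(name: str) -> str:
    stem = name.split("-")[0]
    return {v: k for k, v in _SUBFAMILY_STEM.items()}[stem]


def simulate_te_annotation(config: SimulationConfig) -> tuple[TEAnnotation, dict]:
    """Random TE loci with class-consistent subfamilies and separable
    young/old milliDiv strata; optionally plants a spatially clustered subset
    within a single window for the spatial-null tests.

    Returns (annotation, truth) where truth records young subfamilies and
    the ids of the clustered loci.
    """
    rng = rng_for(config.seed, "te_annotation")
    subs = subfamily_names(config)
    n_young = int(round(config.young_subfamily_fraction * len(subs)))
    young = set(rng.choice(subs, size=n_young, replace=False).tolist())

    rows = []
    for sub in subs:
        mean_md = config.young_millidiv_mean if sub in young else config.old_millidiv_mean
        for j in range(config.loci_per_subfamily):
            chrom = f"chr{rng.integers(1, config.n_chromosomes + 1)}"
            length = int(rng.integers(*config.te_length_range))
            start = int(rng.integers(0, config.chrom_length - length))
            md = max(0.0, float(rng.normal(mean_md, config.millidiv_sd)))
            rows.append(
                {
                    "locus_id": f"{sub}|{chrom}:{start}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "subfamily": sub,
                    "te_class": _subfamily_class(sub),
                    "milli_div": md,
                }
            )

    clustered_ids: list[str] = []
    if config.clustered_n_loci:
        anchor = int(rng.integers(0, config.chrom_length - config.clustered_window))
        sub = subs[0]
        for j in range(config.clustered_n_loci):
            start = anchor + int(rng.integers(0, config.clustered_window - 400))
            locus_id = f"{sub}|chr1:{start}#c{j}"
            rows.append(
                {
                    "locus_id": locus_id,
                    "chrom": "chr1",
                    "start": start,
                    "end": start + 400,
                    "strand": "+",
                    "subfamily": sub,
                    "te_class": _subfamily_class(sub),
                    "milli_div": max(0.0, float(rng.normal(config.young_millidiv_mean, config.millidiv_sd))),
                }
            )
            clustered_ids.append(locus_id)

    df = pd.DataFrame(rows).drop_duplicates("locus_id").reset_index(drop=True)
    truth = {"young_subfamilies": sorted(young), "clustered_loci": clustered_ids}
    return TEAnnotation(df), truth


# ---------------------------------------------------------------------------
# single-cell dataset
# ---------------------------------------------------------------------------

# Shared-factor loading per target Spearman rho, calibrated by Monte-Carlo on
# this generator (log-normalized values, default dispersion/library noise);
# linearly interpolated in between.
_GAIN_RHO = np.array([0.0, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.75])
_GAIN_B = np.array([0.0, 0.12, 0.22, 0.27, 0.31, 0.40, 0.53, 0.62, 0.80, 1.05, 1.45])


def _gain(effect: float) -> float:
    sign = 1.0 if effect >= 0 else -1.0
    return sign * float(np.interp(abs(effect), _GAIN_RHO, _GAIN_B))


def _archetype_profile(archetype: str, n_stages: int, spike_stage: int) -> np.ndarray:
    if archetype == "early_persist":
        prof = np.full(n_stages, 0.4)
        prof[0] = 1.0
    elif archetype == "stage_spike":
        prof = np.full(n_stages, 0.05)
        prof[spike_stage] = 1.0
    elif archetype == "early_decay":
        prof = 0.3 ** np.arange(n_stages)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return prof


def default_archetype_map(config: SimulationConfig) -> dict[str, str]:
    subs = subfamily_names(config)
    n_covered = int(round(config.archetype_fraction * len(subs)))
    return {sub: ARCHETYPES[i % 3] for i, sub in enumerate(subs[:n_covered])}


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_single_cell_dataset(
    config: SimulationConfig, annotation: TEAnnotation | None = None
) -> ad.AnnData:
    """Sparse NB counts for genes, mitochondrial genes and TE loci with
    per-cell library factors, temporal archetypes over stages, planted TF-TE
    latent-factor co-expression, and (optionally) planted QC violations.

    Truth labels live in ``.uns``: planted pairs, archetype map, QC reasons.
    """
    if annotation is None:
        annotation, _ = simulate_te_annotation(config)
    rng = rng_for(config.seed, "single_cell")

    # --- cells -------------------------------------------------------------
    cell_rows = []
    for ct in config.cell_types:
        for stage in config.stages:
            for i in range(config.n_cells_per_group):
                cell_rows.append((f"{ct}|{stage}|{i}", ct, stage))
    obs = pd.DataFrame(cell_rows, columns=["cell_id", "cell_type", "stage"]).set_index("cell_id")
    obs["era"] = np.where(obs["stage"].isin(config.embryonic_stages), "embryonic", "postnatal")
    n_cells = len(obs)
    stage_index = {s: i for i, s in enumerate(config.stages)}

    # --- features ----------------------------------------------------------
    planted_tfs = [tf for tf, _, _ in config.planted_tf_te_pairs]
    gene_names = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    for tf in planted_tfs:
        if tf not in gene_names:
            gene_names.append(tf)
    mito_names = [f"MT-syn{i + 1}" for i in range(config.n_mito_genes)]
    loci = annotation.loci
    locus_ids = loci["locus_id"].tolist()

    var = pd.DataFrame(
        {
            "kind": ["gene"] * len(gene_names)
            + ["mito_gene"] * len(mito_names)
            + ["te_locus"] * len(locus_ids),
            "subfamily": [""] * (len(gene_names) + len(mito_names)) + loci["subfamily"].tolist(),
            "te_class": [""] * (len(gene_names) + len(mito_names)) + loci["te_class"].tolist(),
        },
        index=gene_names + mito_names + locus_ids,
    )

    # --- log-mean structure --------------------------------------------------
    gene_logmu = rng.normal(np.log(3.0), 0.7, size=len(gene_names))
    for tf in planted_tfs:
        gene_logmu[gene_names.index(tf)] = np.log(10.0)
    total_gene_mean = np.exp(gene_logmu).sum()
    f = float(np.mean(config.mito_fraction_range))
    mito_mu = np.full(len(mito_names), f / (1 - f) * total_gene_mean / max(1, len(mito_names)))

    locus_logmu = rng.normal(np.log(0.8), 0.5, size=len(locus_ids))
    sub_of_locus = loci["subfamily"].to_numpy()

    archetypes = (
        dict(config.temporal_archetypes)
        if config.temporal_archetypes is not None
        else default_archetype_map(config)
    )
    spike_stage = (
        config.spike_stage if config.spike_stage is not None else len(config.stages) // 2
    )
    stage_mult = np.ones((len(config.stages), len(locus_ids)))
    for j, sub in enumerate(sub_of_locus):
        arc = archetypes.get(sub)
        if arc is not None:
            stage_mult[:, j] = _archetype_profile(arc, len(config.stages), spike_stage)

    # latent factors for planted TF-TE pairs
    latent = {}
    for tf, sub, eff in config.planted_tf_te_pairs:
        z = rng_for(config.seed, "latent", tf, sub).normal(size=n_cells)
        latent[(tf, sub)] = (z, _gain(eff))

    # --- draw counts ---------------------------------------------------------
    lib = np.exp(rng.normal(0.0, config.library_sd, size=n_cells))
    stage_idx = obs["stage"].map(stage_index).to_numpy()

    gene_mu = np.outer(lib, np.exp(gene_logmu))
    for tf, sub in latent:
        z, b = latent[(tf, sub)]
        gene_mu[:, gene_names.index(tf)] *= np.exp(b * z - b * b / 2.0)
    mito_mu_mat = np.outer(lib, mito_mu)

    te_mu = np.outer(lib, np.exp(locus_logmu)) * stage_mult[stage_idx, :]
    for tf, sub in latent:
        z, b = latent[(tf, sub)]
        cols = np.flatnonzero(sub_of_locus == sub)
        te_mu[:, cols] *= np.exp(b * z - b * b / 2.0)[:, None]

    counts = np.concatenate(
        [
            _nb_counts(rng, gene_mu, config.nb_dispersion),
            _nb_counts(rng, mito_mu_mat, config.nb_dispersion),
            _nb_counts(rng, te_mu, config.nb_dispersion),
        ],
        axis=1,
    ).astype(np.int64)

    # --- planted QC violations ----------------------------------------------
    qc_truth: dict[str, str] = {}
    if config.qc_violation_fraction > 0:
        n_gene_feats = len(gene_names) + len(mito_names)
        n_per_rule = max(1, int(round(config.qc_violation_fraction * n_cells)))
        if 4 * n_per_rule > n_cells:
            raise ValueError("qc_violation_fraction too large for the cell count")
        if config.n_genes <= 7000:
            raise ValueError(
                "planting doublet violations (>7000 genes detected) requires "
                "n_genes > 7000"
            )
        chosen = rng.choice(n_cells, size=4 * n_per_rule, replace=False)
        groups = np.split(chosen, 4)
        for c in groups[0]:  # low UMI
            row = counts[c, :n_gene_feats].astype(float)
            tot = row.sum()
            if tot > 0:
                counts[c, :n_gene_feats] = rng.binomial(
                    counts[c, :n_gene_feats], min(1.0, 1200.0 / tot)
                )
            qc_truth[obs.index[c]] = "low_umi"
        for c in groups[1]:  # few genes detected, UMI kept high
            counts[c, : len(gene_names)] = 0
            keep = rng.choice(len(gene_names), size=50, replace=False)
            counts[c, keep] = 60
            qc_truth[obs.index[c]] = "low_genes"
        for c in groups[2]:  # high mitochondrial fraction
            tot = counts[c].sum()
            counts[c, len(gene_names) : n_gene_feats] = int(
                np.ceil(0.12 * tot / max(1, len(mito_names)))
            )
            qc_truth[obs.index[c]] = "high_mito"
        for c in groups[3]:  # doublet-like breadth
            counts[c, : min(7200, len(gene_names))] = np.maximum(
                counts[c, : min(7200, len(gene_names))], 1
            )
            qc_truth[obs.index[c]] = "doublet"

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=var,
    )
    adata.uns["truth"] = {
        "planted_tf_te_pairs": [list(p) for p in config.planted_tf_te_pairs],
        "archetypes": archetypes,
        "qc_reasons": qc_truth,
    }
    return adata


# ---------------------------------------------------------------------------
# regulatory interval fixtures
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryFixtures:
    motifs: dict[str, PeakSet]  # TF -> motif occurrence intervals
    marks: dict[str, PeakSet]  # H3K27ac / H3K4me1 / H3K4me3
    tss: PeakSet
    gene_model: dict[str, PeakSet]  # exon / 5UTR / 3UTR / intron
    truth: dict  # regulatory_call and genomic_context labels per planted locus


_MARK_NAMES = ("H3K27ac", "H3K4me1", "H3K4me3")

# (ac, me1, me3, tss_near) -> expected call; the 8 mark combinations are each
# exercised with both TSS placements by cycling through this table.
_REG_CASES = [
    (True, True, False, False, "enhancer"),
    (True, False, True, True, "promoter"),
    (True, False, True, False, "neither"),  # promoter marks but TSS too far
    (True, True, True, True, "neither"),
    (False, True, False, False, "neither"),
    (False, False, True, True, "neither"),
    (True, False, False, False, "neither"),
    (False, False, False, False, "neither"),
    (False, True, True, True, "neither"),
]

_CONTEXT_CASES = ["exon", "5UTR", "3UTR", "intron", "intergenic", "exon+intron"]


def _spaced_loci(annotation: TEAnnotation, min_gap: int = 20_000) -> pd.DataFrame:
    """Subset of loci whose middles are >= min_gap from any other locus,
    so per-locus fixtures cannot interfere with each other."""
    from .intervals import min_middle_distances

    d = min_middle_distances(annotation.loci)
    return annotation.loci[d >= min_gap].reset_index(drop=True)


def simulate_regulatory_fixtures(
    annotation: TEAnnotation, config: SimulationConfig
) -> RegulatoryFixtures:
    """Motif occurrences for planted TFs plus histone-mark/TSS/gene-model
    fixtures with known truth labels.

    Motifs are placed in ``config.motif_fraction`` of the loci of each
    planted pair's subfamily. Histone peaks and TSS are built on widely
    spaced loci so each locus realizes exactly one designed mark/TSS case.
    """
    rng = rng_for(config.seed, "regulatory")

    motifs: dict[str, PeakSet] = {}
    motif_truth: dict[str, dict] = {}
    for tf, sub, _ in config.planted_tf_te_pairs:
        sub_loci = annotation.subfamily_loci(sub)
        n_hit = int(round(config.motif_fraction * len(sub_loci)))
        hit = sub_loci.iloc[
            np.sort(rng.choice(len(sub_loci), size=n_hit, replace=False))
        ]
        rows = []
        for r in hit.itertuples(index=False):
            pos = int(rng.integers(r.start, max(r.start + 1, r.end - 10)))
            rows.append({"chrom": r.chrom, "start": pos, "end": pos + 10})
        motifs[tf] = PeakSet.from_frame(f"motif:{tf}", pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        motif_truth[tf] = {"subfamily": sub, "fraction": n_hit / len(sub_loci),
                           "hit_loci": hit["locus_id"].tolist()}

    spaced = _spaced_loci(annotation)
    needed = len(_REG_CASES) + len(_CONTEXT_CASES)
    if len(spaced) < needed:
        raise ValueError("annotation too dense to place independent regulatory fixtures")
    pick = spaced.iloc[: needed].reset_index(drop=True)
    reg_loci = pick.iloc[: len(_REG_CASES)]
    ctx_loci = pick.iloc[len(_REG_CASES):].reset_index(drop=True)

    mark_rows: dict[str, list] = {m: [] for m in _MARK_NAMES}
    tss_rows: list[dict] = []
    call_truth: dict[str, str] = {}
    for (ac, me1, me3, near, call), r in zip(_REG_CASES, reg_loci.itertuples(index=False)):
        for flag, mark in zip((ac, me1, me3), _MARK_NAMES):
            if flag:
                mark_rows[mark].append(
                    {"chrom": r.chrom, "start": max(0, r.start - 50), "end": r.end + 50}
                )
        if near:
            pos = r.end + 400
            tss_rows.append({"chrom": r.chrom, "start": pos, "end": pos + 1})
        call_truth[r.locus_id] = call

    marks = {
        m: PeakSet.from_frame(m, pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        for m, rows in mark_rows.items()
    }
    tss = PeakSet.from_frame("TSS", pd.DataFrame(tss_rows, columns=["chrom", "start", "end"]))

    gm_rows: dict[str, list] = {k: [] for k in ("exon", "5UTR", "3UTR", "intron")}
    ctx_truth: dict[str, str] = {}
    for case, r in zip(_CONTEXT_CASES, ctx_loci.itertuples(index=False)):
        regions = case.split("+") if case != "intergenic" else []
        for region in regions:
            gm_rows[region].append(
                {"chrom": r.chrom, "start": max(0, r.start - 20), "end": r.end + 20}
            )
        ctx_truth[r.locus_id] = regions[0] if regions else "intergenic"

    gene_model = {
        k: PeakSet.from_frame(k, pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        for k, rows in gm_rows.items()
    }

    truth = {
        "regulatory_call": call_truth,
        "genomic_context": ctx_truth,
        "motifs": motif_truth,
    }
    return RegulatoryFixtures(motifs=motifs, marks=marks, tss=tss, gene_model=gene_model, truth=truth)


# ---------------------------------------------------------------------------
# WT/KO bulk experiment
# ---------------------------------------------------------------------------

def simulate_ko_experiment(
    annotation: TEAnnotation,
    config: SimulationConfig,
    regulator: str,
    regulated_loci: Mapping[str, float] | None = None,
) -> tuple[BulkExperiment, dict[str, str]]:
    """Per-locus NB counts for WT and KO arms with planted log2(WT/KO)
    effects, a stratum of loci kept below the TPM filter in every sample,
    and emitted truth labels {induced, repressed, neutral, low_expression}.

    ``regulated_loci`` maps locus_id -> planted log2FC; when None, the
    entries of ``config.planted_ko_effects`` for this regulator are used.
    """
    if config.ko_replicates < 2:
        raise ValueError("need >= 2 replicates per arm")
    rng = rng_for(config.seed, "ko", regulator)
    loci = annotation.loci
    n = len(loci)

    if regulated_loci is None:
        regulated_loci = {
            locus: fc for (reg, locus), fc in config.planted_ko_effects.items() if reg == regulator
        }
    unknown = set(regulated_loci) - set(loci["locus_id"])
    if unknown:
        raise ValueError(f"planted loci absent from annotation: {sorted(unknown)[:5]}")

    base = np.exp(rng.normal(config.ko_base_log_mean, 0.6, size=n))
    n_low = int(round(config.low_expression_fraction * n))
    eligible = np.array([lid not in regulated_loci for lid in loci["locus_id"]])
    low_idx = rng.choice(np.flatnonzero(eligible), size=n_low, replace=False) if n_low else np.array([], dtype=int)
    base[low_idx] = 0.0  # never observed -> below any TPM threshold in all samples

    log2fc = np.zeros(n)
    id_to_row = {lid: i for i, lid in enumerate(loci["locus_id"])}
    for lid, fc in regulated_loci.items():
        log2fc[id_to_row[lid]] = fc

    wt_mu = base
    ko_mu = base * np.power(2.0, -log2fc)

    def _arm(mu: np.ndarray, prefix: str) -> pd.DataFrame:
        cols = {}
        for r in range(config.ko_replicates):
            lib = float(np.exp(rng.normal(0.0, 0.05)))
            cols[f"{prefix}{r + 1}"] = _nb_counts(rng, mu * lib, config.ko_dispersion)
        return pd.DataFrame(cols, index=loci["locus_id"])

    wt_counts = _arm(wt_mu, "WT")
    ko_counts = _arm(ko_mu, "KO")

    def _tpm(df: pd.DataFrame) -> pd.DataFrame:
        tot = df.sum(axis=0).replace(0, 1)
        return df / tot * 1e6

    exp = BulkExperiment(
        regulator=regulator,
        wt_counts=wt_counts,
        ko_counts=ko_counts,
        wt_tpm=_tpm(wt_counts),
        ko_tpm=_tpm(ko_counts),
    )

    truth: dict[str, str] = {}
    for lid, i in id_to_row.items():
        if i in set(low_idx.tolist()):
            truth[lid] = "low_expression"
        elif log2fc[i] > 0:
            truth[lid] = "induced"
        elif log2fc[i] < 0:
            truth[lid] = "repressed"
        else:
            truth[lid] = "neutral"
    return exp, truth


# ---------------------------------------------------------------------------
# diversity populations
# ---------------------------------------------------------------------------

def simulate_diversity_dataset(
    seed: int = 0,
    n_subfamilies: int = 60,
    n_cells: int = 200,
    homogeneous_repertoires: Sequence[int] = (10, 20, 40, 60),
    mosaic_repertoire: int = 60,
    mosaic_cell_fraction: float = 0.1,
) -> ad.AnnData:
    """Populations contrasting homogeneous and mosaic TE expression.

    Homogeneous populations ("pDC-like") have every cell expressing the
    population's whole repertoire, with repertoire sizes spanning a range so
    the per-cell vs population entropy relation is well defined. The mosaic
    population ("mTEC-like") has a broad repertoire but each cell expresses
    only a small random subset, so its population entropy sits far above the
    value its median per-cell entropy predicts (positive delta_y).

    Returns an AnnData with te_subfamily features and per-cell ``cell_type``
    / ``era`` metadata (all postnatal).
    """
    rng = rng_for(seed, "diversity")
    subs = [f"div-s{i + 1}" for i in range(n_subfamilies)]
    blocks, pops = [], []
    for size in homogeneous_repertoires:
        C = np.zeros((n_cells, n_subfamilies))
        C[:, :size] = rng.poisson(5.0, size=(n_cells, size)) + 1
        blocks.append(C)
        pops += [f"homog-{size}"] * n_cells
    k = max(1, int(round(mosaic_cell_fraction * mosaic_repertoire)))
    C = np.zeros((n_cells, n_subfamilies))
    for i in range(n_cells):
        on = rng.choice(mosaic_repertoire, size=k, replace=False)
        C[i, on] = rng.poisson(5.0, size=k) + 1
    blocks.append(C)
    pops += ["mosaic"] * n_cells

    X = np.vstack(blocks)
    var = pd.DataFrame(
        {"kind": "te_subfamily", "subfamily": subs, "te_class": "LINE"}, index=subs
    )
    obs = pd.DataFrame(
        {"cell_type": pops, "era": "postnatal"},
        index=[f"cell{i}" for i in range(len(pops))],
    )
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
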