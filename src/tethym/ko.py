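"""Characterization of TE loci regulated by AIRE, FEZF2, and CHD4.

Given WT/KO bulk tables over TE loci: low-TPM filtering, induced/repressed
classification on log2(WT/KO) with a pooled-variance t-test and BH
correction, regulator-set overlaps, class/subfamily composition enrichment
against the genome-wide annotation background (chi-squared with Bonferroni),
spatial clustering of regulated loci against matched-size random sets,
genomic localization, and sequence-age comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import stat_kernel as sk
from ._rng import rng_for
from .intervals import (
    TEAnnotation,
    assign_genomic_context,
    min_middle_distances,
    te_locus_age,
)

__all__ = [
    "BulkExperiment",
    "age_profile",
    "classify_regulation",
    "composition_enrichment",
    "filter_low_expression",
    "localization_profile",
    "regulator_set_overlap",
    "spatial_clustering_test",
]


@dataclass
class BulkExperiment:
    """WT and KO count/TPM tables sharing a locus index."""

    regulator: str
    wt_counts: pd.DataFrame
    ko_counts: pd.DataFrame
    wt_tpm: pd.DataFrame
    ko_tpm: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.wt_tpm.index.equals(self.ko_tpm.index):
            raise ValueError("WT and KO arms must share the same locus index")
        if self.wt_tpm.shape[1] < 2 or self.ko_tpm.shape[1] < 2:
            raise ValueError("need >= 2 replicates per arm")

    @property
    def loci(self) -> pd.Index:
        return self.wt_tpm.index

    def subset(self, loci: Sequence[str]) -> "BulkExperiment":
        return BulkExperiment(
            regulator=self.regulator,
            wt_counts=self.wt_counts.loc[loci],
            ko_counts=self.ko_counts.loc[loci],
            wt_tpm=self.wt_tpm.loc[loci],
            ko_tpm=self.ko_tpm.loc[loci],
        )


def filter_low_expression(experiment: BulkExperiment, tpm_min: float = 2.0) -> BulkExperiment:
    """Drop loci whose TPM is below ``tpm_min`` in every sample of both arms."""
    tpm = pd.concat([experiment.wt_tpm, experiment.ko_tpm], axis=1)
    keep = (tpm >= tpm_min).any(axis=1)
    return experiment.subset(experiment.loci[keep])


def classify_regulation(
    experiment: BulkExperiment,
    fc_cut: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-locus log2(WT/KO) classification into induced/repressed/neutral.

    log2fc = log2((mean WT TPM + pseudocount) / (mean KO TPM + pseudocount));
    p-values from a pooled-variance two-sample t-test on log2(TPM +
    pseudocount), BH-adjusted across loci. ``fc_cut`` is on the log2 scale
    (the default 2 means a 4-fold change).

    Returns a frame indexed by locus_id with columns log2fc, p, adj_p,
    status.
    """
    wt = np.log2(experiment.wt_tpm.to_numpy(dtype=float) + pseudocount)
    ko = np.log2(experiment.ko_tpm.to_numpy(dtype=float) + pseudocount)
    log2fc = np.log2(experiment.wt_tpm.mean(axis=1) + pseudocount) - np.log2(
        experiment.ko_tpm.mean(axis=1) + pseudocount
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(wt, ko, axis=1, equal_var=True)
    p = np.asarray(p, dtype=float)
    # zero variance in both arms with equal means: no evidence of change
    degenerate = np.isnan(p)
    p[degenerate] = 1.0

    adj = sk.adjust_pvalues(p, method="benjamini_hochberg").adjusted
    status = np.full(len(p), "neutral", dtype=object)
    status[(log2fc.to_numpy() >= fc_cut) & (adj <= alpha)] = "induced"
    status[(log2fc.to_numpy() <= -fc_cut) & (adj <= alpha)] = "repressed"

    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj, "status": status},
        index=experiment.loci,
    )


def regulator_set_overlap(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise overlap percentages of induced and repressed locus sets.

    For each ordered regulator pair (A, B) and direction, reports
    100 * |A ∩ B| / |A|. Empty reference sets report 0 with a warning.
    """
    if len(results) < 2:
        raise ValueError("need results for >= 2 regulators")
    rows = []
    for direction in ("induced", "repressed"):
        sets = {
            reg: set(df.index[df["status"] == direction]) for reg, df in results.items()
        }
        for a, sa in sets.items():
            for b, sb in sets.items():
                if a == b:
                    continue
                if not sa:
                    warnings.warn(f"{a} has no {direction} loci; overlap reported as 0")
                    pct = 0.0
                else:
                    pct = 100.0 * len(sa & sb) / len(sa)
                rows.append(
                    {"direction": direction, "reference": a, "other": b,
                     "n_reference": len(sa), "n_shared": len(sa & sb), "overlap_pct": pct}
                )
    return pd.DataFrame(rows)


def composition_enrichment(
    regulated: Sequence[str],
    annotation: TEAnnotation,
    by: Literal["te_class", "subfamily"] = "subfamily",
) -> pd.DataFrame:
    """Composition of a regulated locus set versus the genome-wide
    annotation background.

    Per category, a 1-df chi-squared goodness-of-fit of [in, out] counts
    against the background proportions; Bonferroni across the categories
    tested. Categories whose expected in-set count is below 1 are pooled
    into ``other``.
    """
    regulated = list(regulated)
    if not regulated:
        raise ValueError("empty regulated set")
    loci = annotation.loci.set_index("locus_id")
    missing = set(regulated) - set(loci.index)
    if missing:
        raise ValueError(f"regulated loci absent from annotation: {sorted(missing)[:5]}")

    bg = loci[by].value_counts()
    bg_prop = bg / bg.sum()
    obs = loci.loc[regulated, by].value_counts()
    n_set = len(regulated)

    expected = bg_prop * n_set
    small = expected[expected < 1].index
    categories = [c for c in bg_prop.index if c not in set(small)]
    pooled_prop = float(bg_prop.loc[list(small)].sum()) if len(small) else 0.0

    rows = []
    for cat in categories:
        p_cat = float(bg_prop[cat])
        o_in = int(obs.get(cat, 0))
        stat, p = sk.chi_squared_gof([o_in, n_set - o_in], [p_cat, 1 - p_cat])
        rows.append(
            {"category": cat, "observed": o_in, "expected": p_cat * n_set,
             "set_proportion": o_in / n_set, "background_proportion": p_cat,
             "stat": stat, "p": p}
        )
    if pooled_prop >= 1.0:
        warnings.warn(
            "set too small: every category expects < 1 locus; nothing to test"
        )
    elif pooled_prop > 0:
        o_in = int(obs.reindex(small).fillna(0).sum())
        stat, p = sk.chi_squared_gof([o_in, n_set - o_in], [pooled_prop, 1 - pooled_prop])
        rows.append(
            {"category": "other", "observed": o_in, "expected": pooled_prop * n_set,
             "set_proportion": o_in / n_set, "background_proportion": pooled_prop,
             "stat": stat, "p": p}
        )
    columns = [
        "category", "observed", "expected", "set_proportion",
        "background_proportion", "stat", "p",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df["adj_p"] = sk.adjust_pvalues(df["p"].to_numpy(), method="bonferroni").adjusted
    return df


@dataclass
class SpatialClusteringResult:
    observed: np.ndarray  # finite min-middle-distances of the regulated set
    random_pooled: np.ndarray  # pooled distances over the random sets
    p: float
    n_random_sets: int


def spatial_clustering_test(
    regulated: Sequence[str],
    annotation: TEAnnotation,
    n_random_sets: int = 100,
    seed: int = 0,
) -> SpatialClusteringResult:
    """Are regulated loci closer together than matched-size random sets?

    Random sets of equal cardinality are drawn without replacement from the
    non-regulated loci; minimal middle-to-middle distances on the same
    chromosome are compared by a two-sided rank-sum test against the pooled
    random distances.
    """
    regulated = list(regulated)
    if len(regulated) < 2:
        raise ValueError("regulated set must contain >= 2 loci")
    loci = annotation.loci.set_index("locus_id")
    reg_df = loci.loc[regulated]
    background = loci.drop(index=regulated)
    if len(background) < len(regulated):
        raise ValueError("not enough non-regulated loci to draw matched random sets")

    obs = min_middle_distances(reg_df.reset_index())
    obs = obs[np.isfinite(obs)]

    rng = rng_for(seed, "spatial_null")
    pooled = []
    bg_idx = np.arange(len(background))
    for _ in range(n_random_sets):
        take = rng.choice(bg_idx, size=len(regulated), replace=False)
        d = min_middle_distances(background.iloc[take].reset_index())
        pooled.append(d[np.isfinite(d)])
    random_pooled = np.concatenate(pooled) if pooled else np.array([])

    if obs.size == 0 or random_pooled.size == 0:
        raise ValueError("no finite distances to compare")
    _, p = sk.wilcoxon_rank_sum(obs, random_pooled)
    return SpatialClusteringResult(
        observed=obs, random_pooled=random_pooled, p=float(p), n_random_sets=n_random_sets
    )


def localization_profile(
    regulated: Sequence[str],
    gene_model: Mapping[str, object],
    annotation: TEAnnotation,
) -> pd.DataFrame:
    """Genomic-region proportions of a regulated set with a chi-squared
    goodness-of-fit against the all-loci background."""
    regulated = list(regulated)
    loci = annotation.loci.set_index("locus_id")
    all_labels = pd.Series(
        assign_genomic_context(annotation.loci, gene_model), index=annotation.loci["locus_id"]
    )
    cats = ["exon", "5UTR", "3UTR", "intron", "intergenic"]
    bg_counts = all_labels.value_counts().reindex(cats).fillna(0)
    obs_counts = all_labels.loc[regulated].value_counts().reindex(cats).fillna(0)

    usable = bg_counts > 0
    if usable.sum() < 2:
        # a one-category background always fits itself
        stat, p = 0.0, 1.0
    else:
        props = (bg_counts[usable] / bg_counts[usable].sum()).to_numpy()
        stat, p = sk.chi_squared_gof(obs_counts[usable].to_numpy(), props)

    out = pd.DataFrame(
        {
            "region": cats,
            "observed": obs_counts.to_numpy(),
            "proportion": obs_counts.to_numpy() / max(1, len(regulated)),
            "background_proportion": (bg_counts / bg_counts.sum()).to_numpy(),
        }
    )
    out.attrs["chi2_stat"] = stat
    out.attrs["chi2_p"] = p
    return out


def age_profile(
    regulated: Sequence[str],
    annotation: TEAnnotation,
    species_rate: float,
) -> dict:
    """Age distributions (years) for regulated vs background loci with a
    two-sided rank-sum comparison; a singleton set skips the test."""
    regulated = list(regulated)
    loci = annotation.loci.set_index("locus_id")
    reg_ages = te_locus_age(loci.loc[regulated, "milli_div"].to_numpy(), species_rate)
    bg_ages = te_locus_age(
        loci.drop(index=regulated)["milli_div"].to_numpy(), species_rate
    )
    if len(reg_ages) < 2 or len(bg_ages) < 2:
        warnings.warn("too few loci for an age comparison; test skipped")
        return {"regulated_ages": reg_ages, "background_ages": bg_ages, "p": float("nan")}
    _, p = sk.wilcoxon_rank_sum(reg_ages, bg_ages)
    return {
        "regulated_ages": reg_ages,
        "background_ages": bg_ages,
        "regulated_median": float(np.median(reg_ages)),
        "background_median": float(np.median(bg_ages)),
        "p": float(p),
    }
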