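"""Genomic-interval engine and annotation I/O.

Coordinates are 0-based half-open (BED convention) throughout; the
RepeatMasker-style table reader converts 1-based starts on load. Strand is
ignored in all overlap computations. Overlap means >= 1 shared base between
half-open intervals on the same chromosome.

TE loci carry a RepeatMasker ``milliDiv`` (mismatches per thousand bases vs
the subfamily consensus), from which locus age in years is estimated as
``(milliDiv / 1000) / substitution_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "TEAnnotation",
    "TELocus",
    "assign_genomic_context",
    "distance_to_nearest_tss",
    "intersect_any",
    "min_middle_distances",
    "peak_te_overlap_fraction",
    "read_bed",
    "read_narrowpeak",
    "read_repeatmasker_table",
    "read_tss_bed",
    "te_locus_age",
    "write_bed",
    "write_repeatmasker_table",
]

TE_CLASSES = ("LINE", "LTR", "SINE")

HUMAN_SUBSTITUTION_RATE = 2.2e-9  # substitutions per site per year
MOUSE_SUBSTITUTION_RATE = 4.5e-9


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def middle(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TELocus:
    interval: GenomicInterval
    locus_id: str
    subfamily: str
    te_class: str
    milli_div: float

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if self.milli_div < 0:
            raise ValueError("milliDiv must be non-negative")


def _interval_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


@dataclass
class PeakSet:
    """A named set of intervals (ChIP peaks, motif occurrences, TSS, ...)."""

    mark_or_factor: str
    intervals: pd.DataFrame  # columns chrom, start, end[, strand]; sorted on load

    @classmethod
    def from_intervals(cls, name: str, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        return cls(mark_or_factor=name, intervals=_interval_frame(intervals))

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "PeakSet":
        df = df.loc[:, [c for c in ("chrom", "start", "end", "strand") if c in df.columns]]
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        return cls(mark_or_factor=name, intervals=df)

    def __len__(self) -> int:
        return len(self.intervals)


class TEAnnotation:
    """RepeatMasker-style TE locus table with subfamily and position indices."""

    COLUMNS = ["locus_id", "chrom", "start", "end", "strand", "subfamily", "te_class", "milli_div"]

    def __init__(self, loci: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in loci.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if loci["locus_id"].duplicated().any():
            dup = loci.loc[loci["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise ValueError(f"duplicate locus_id {dup!r}")
        # a subfamily must map to a single class
        cls_per_sub = loci.groupby("subfamily")["te_class"].nunique()
        bad = cls_per_sub[cls_per_sub > 1]
        if len(bad):
            raise ValueError(f"subfamilies mapped to multiple classes: {list(bad.index)}")
        self.loci = loci.loc[:, self.COLUMNS].reset_index(drop=True)
        self._by_subfamily = {
            sub: idx.to_numpy() for sub, idx in self.loci.groupby("subfamily").groups.items()
        }

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def subfamilies(self) -> list[str]:
        return sorted(self._by_subfamily)

    def subfamily_class_map(self) -> dict[str, str]:
        return dict(self.loci.drop_duplicates("subfamily").set_index("subfamily")["te_class"])

    def subfamily_loci(self, subfamily: str) -> pd.DataFrame:
        if subfamily not in self._by_subfamily:
            raise KeyError(f"unknown subfamily {subfamily!r}")
        return self.loci.iloc[self._by_subfamily[subfamily]]

    def intervals(self) -> pd.DataFrame:
        return self.loci[["chrom", "start", "end"]]

    def records(self) -> list[TELocus]:
        return [
            TELocus(
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
                locus_id=r.locus_id,
                subfamily=r.subfamily,
                te_class=r.te_class,
                milli_div=float(r.milli_div),
            )
            for r in self.loci.itertuples(index=False)
        ]


# ---------------------------------------------------------------------------
# core interval algebra (numpy sorted-array sweeps)
# ---------------------------------------------------------------------------

def _coerce_frame(x) -> pd.DataFrame:
    if isinstance(x, PeakSet):
        return x.intervals
    if isinstance(x, TEAnnotation):
        return x.intervals()
    if isinstance(x, pd.DataFrame):
        return x
    return _interval_frame(x)


def intersect_any(query, subject) -> np.ndarray:
    """Boolean per query interval: does it share >= 1 bp with any subject?

    Strand-agnostic; empty inputs yield all-False.
    """
    q = _coerce_frame(query)
    s = _coerce_frame(subject)
    out = np.zeros(len(q), dtype=bool)
    if len(q) == 0 or len(s) == 0:
        return out
    for chrom, s_chr in s.groupby("chrom"):
        q_mask = (q["chrom"] == chrom).to_numpy()
        if not q_mask.any():
            continue
        order = np.argsort(s_chr["start"].to_numpy(), kind="mergesort")
        starts = s_chr["start"].to_numpy()[order]
        ends = s_chr["end"].to_numpy()[order]
        max_end = np.maximum.accumulate(ends)
        q_start = q.loc[q_mask, "start"].to_numpy()
        q_end = q.loc[q_mask, "end"].to_numpy()
        # candidates: subject.start < query.end; hit if running max end > query.start
        idx = np.searchsorted(starts, q_end, side="left")
        hit = np.zeros(q_start.shape, dtype=bool)
        nz = idx > 0
        hit[nz] = max_end[idx[nz] - 1] > q_start[nz]
        out[q_mask] = hit
    return out


def peak_te_overlap_fraction(peaks: PeakSet, annotation: TEAnnotation) -> float:
    """Fraction of peaks overlapping at least one TE locus."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    hits = intersect_any(peaks, annotation)
    return float(hits.mean())


def _gap_distances(q_start, q_end, positions_start, positions_end) -> np.ndarray:
    """Min gap distance per query to a set of same-chromosome intervals."""
    order = np.argsort(positions_start, kind="mergesort")
    starts = positions_start[order]
    ends_sorted_by_start = positions_end[order]
    max_end = np.maximum.accumulate(ends_sorted_by_start)
    ends = np.sort(positions_end)
    out = np.empty(len(q_start), dtype=float)
    for i, (qs, qe) in enumerate(zip(q_start, q_end)):
        # overlap?
        k = np.searchsorted(starts, qe, side="left")
        if k > 0 and max_end[k - 1] > qs:
            out[i] = 0.0
            continue
        best = math.inf
        # nearest interval entirely to the left: largest end <= qs
        j = np.searchsorted(ends, qs, side="right")
        if j > 0:
            best = min(best, qs - ends[j - 1])
        # nearest interval entirely to the right: smallest start >= qe
        if k < len(starts):
            best = min(best, starts[k] - qe)
        out[i] = best
    return out


def distance_to_nearest_tss(loci, tss: PeakSet) -> np.ndarray:
    """Gap distance from each locus to the nearest same-chromosome TSS.

    0 when a TSS falls inside the locus; ``inf`` when the chromosome has no
    TSS. Accepts a TEAnnotation, a PeakSet, a frame, or a single TELocus.
    """
    single = isinstance(loci, TELocus)
    if single:
        iv = loci.interval
        q = pd.DataFrame({"chrom": [iv.chrom], "start": [iv.start], "end": [iv.end]})
    else:
        q = _coerce_frame(loci)
    t = _coerce_frame(tss)
    out = np.full(len(q), math.inf)
    for chrom, t_chr in t.groupby("chrom"):
        q_mask = (q["chrom"] == chrom).to_numpy()
        if not q_mask.any():
            continue
        out[q_mask] = _gap_distances(
            q.loc[q_mask, "start"].to_numpy(),
            q.loc[q_mask, "end"].to_numpy(),
            t_chr["start"].to_numpy(),
            t_chr["end"].to_numpy(),
        )
    return out[0] if single else out


def min_middle_distances(loci) -> np.ndarray:
    """Per locus, the minimal |middle - middle| to another locus on the same
    chromosome; ``inf`` for a chromosome singleton.

    Middle = floor((start + end) / 2).
    """
    df = _coerce_frame(loci)
    if len(df) == 0:
        raise ValueError("need at least one locus")
    mids = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(float)
    out = np.full(len(df), math.inf)
    chroms = df["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        m = mids[mask]
        if m.size < 2:
            continue
        order = np.argsort(m, kind="mergesort")
        ms = m[order]
        d = np.diff(ms)
        best = np.full(m.size, math.inf)
        best[:-1] = d
        best[1:] = np.minimum(best[1:], d)
        res = np.empty_like(best)
        res[order] = best
        out[mask] = res
    return out


def te_locus_age(milli_div, species_rate: float):
    """Estimated locus age in years: (milliDiv / 1000) / substitution rate.

    milliDiv counts mismatches per thousand bases, so it is converted to a
    per-base divergence fraction before dividing by the per-year rate.
    """
    if species_rate <= 0:
        raise ValueError("substitution rate must be positive")
    md = np.asarray(milli_div, dtype=float)
    if np.any(md < 0):
        raise ValueError("milliDiv must be non-negative")
    age = (md / 1000.0) / species_rate
    return float(age) if np.isscalar(milli_div) else age


def subfamily_ages(annotation: TEAnnotation, species_rate: float) -> pd.Series:
    """Mean locus age per subfamily, in years."""
    ages = te_locus_age(annotation.loci["milli_div"].to_numpy(), species_rate)
    return pd.Series(ages, index=annotation.loci["subfamily"]).groupby(level=0).mean()


CONTEXT_PRIORITY = ("exon", "5UTR", "3UTR", "intron")


def assign_genomic_context(loci, gene_model: Mapping[str, object]) -> np.ndarray:
    """Label each locus exon/5UTR/3UTR/intron by overlap priority, else
    intergenic.

    ``gene_model`` maps region names ("exon", "5UTR", "3UTR", "intron") to
    interval sets (PeakSet / frame / iterable of GenomicInterval).
    """
    df = _coerce_frame(loci)
    labels = np.full(len(df), "intergenic", dtype=object)
    unassigned = np.ones(len(df), dtype=bool)
    for region in CONTEXT_PRIORITY:
        if region not in gene_model:
            continue
        hits = intersect_any(df, gene_model[region])
        take = hits & unassigned
        labels[take] = region
        unassigned &= ~take
    return labels


# ---------------------------------------------------------------------------
# I/O (plain-text BED dialects and RepeatMasker-style tables)
# ---------------------------------------------------------------------------

def read_bed(path, name: str | None = None) -> PeakSet:
    """Read BED3-BED6; extra columns beyond the first six are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: min(df.shape[1], 6)]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    keep = ["chrom", "start", "end"] + (["strand"] if "strand" in df.columns else [])
    return PeakSet.from_frame(name or Path(path).stem, df[keep])


def read_narrowpeak(path, name: str | None = None) -> PeakSet:
    """Read ENCODE narrowPeak; only the first six columns are used."""
    return read_bed(path, name=name)


def read_tss_bed(path) -> PeakSet:
    return read_bed(path, name="TSS")


def write_bed(peaks: PeakSet | pd.DataFrame, path) -> None:
    """Write a sorted BED3/BED6 file."""
    df = _coerce_frame(peaks).copy()
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    cols = ["chrom", "start", "end"]
    if "strand" in df.columns:
        df["name"] = "."
        df["score"] = 0
        cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_repeatmasker_table(path) -> TEAnnotation:
    """Read a RepeatMasker-style TE table (1-based starts converted to
    0-based half-open on load).

    Expected tab-separated columns with header:
    locus_id, chrom, start, end, strand, subfamily, te_class, milli_div.
    """
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return TEAnnotation(df)


def write_repeatmasker_table(annotation: TEAnnotation, path) -> None:
    """Write the annotation as a RepeatMasker-style table (1-based starts)."""
    df = annotation.loci.copy()
    df["start"] = df["start"].astype(int) + 1
    df.to_csv(path, sep="\t", index=False)
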