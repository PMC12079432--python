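"""Core genomic types and interval arithmetic.

Coordinates are BED-convention 0-based half-open everywhere; 1-based
coordinates appear only at text boundaries that require them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval: 0-based inclusive ``start``, exclusive ``end``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class AnnotationCategory(str, Enum):
    PROMOTER = "promoter"
    EXON = "exon"
    INTRON = "intron"
    UTR5 = "utr5"
    UTR3 = "utr3"
    DISTAL_INTERGENIC = "distal_intergenic"


#: default precedence when a peak overlaps multiple gene features
ANNOTATION_PRIORITY = (
    AnnotationCategory.PROMOTER,
    AnnotationCategory.UTR5,
    AnnotationCategory.UTR3,
    AnnotationCategory.EXON,
    AnnotationCategory.INTRON,
    AnnotationCategory.DISTAL_INTERGENIC,
)


@dataclass
class GeneModel:
    """A gene with TSS and exon structure.

    The TSS is ``interval.start`` for + strand genes and ``interval.end - 1``
    for - strand genes.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError("gene strand must be + or -")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"exon {ex} outside gene interval for {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class Peak:
    """An accessibility peak with optional annotation fields."""

    id: str
    interval: GenomicInterval
    summit_offset: int | None = None
    gc: float | None = None
    score: float = 0.0
    annotation: AnnotationCategory | None = None
    closest_gene: str | None = None
    dist_to_tss: int | None = None

    def __post_init__(self) -> None:
        if self.gc is not None and not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc must lie in [0, 1], got {self.gc}")


@dataclass
class CountMatrix:
    """A feature-by-sample matrix of nonnegative integer counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        groups = {self.sample_groups[s] for s in self.sample_ids}
        for g in groups:
            if not any(self.sample_groups[s] == g for s in self.sample_ids):
                raise ValueError(f"condition {g} has no samples")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_groups[s] == group]

    def subset_features(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx],
            sample_groups=dict(self.sample_groups),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(
    intervals: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals.

    Intervals sharing >= 1 bp or directly abutting are merged; the output
    is sorted by (chrom, start), disjoint, and covers exactly the union
    of input base pairs.
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = (
        ordered[0].chrom,
        ordered[0].start,
        ordered[0].end,
    )
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def consensus_union(
    peaks_a: list[GenomicInterval], peaks_b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Union of two peak sets: overlapping intervals collapsed into one.

    Mirrors consensus-peak construction across two conditions: the output
    covers exactly the base pairs covered by either input.
    """
    _warn_mixed_chrom_styles(peaks_a, peaks_b)
    return merge_intervals(list(peaks_a) + list(peaks_b))


def _warn_mixed_chrom_styles(*interval_lists) -> None:
    chroms = {iv.chrom for ivs in interval_lists for iv in ivs}
    prefixed = {c for c in chroms if c.startswith("chr")}
    if prefixed and prefixed != chroms:
        warnings.warn(
            "mixed chromosome naming styles (with and without 'chr' prefix); "
            "possible assembly mismatch",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# annotation


def _tss_distance_to_interval(tss: int, iv: GenomicInterval) -> int:
    """Unsigned distance from a TSS base to the nearest base of an interval."""
    if iv.start <= tss < iv.end:
        return 0
    if tss < iv.start:
        return iv.start - tss
    return tss - (iv.end - 1)


def closest_tss(
    position: int, chrom: str, genes: list[GeneModel]
) -> tuple[GeneModel | None, int | None]:
    """Gene with TSS nearest ``position`` on ``chrom``.

    Returns (gene, signed distance); distance is negative when the position
    lies upstream of the TSS in the gene's orientation.  Ties break toward
    the lexicographically smaller gene_id.
    """
    best: GeneModel | None = None
    best_abs: int | None = None
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        d = abs(position - g.tss)
        if (
            best_abs is None
            or d < best_abs
            or (d == best_abs and g.gene_id < best.gene_id)
        ):
            best, best_abs = g, d
    if best is None:
        return None, None
    if best.strand == "+":
        signed = position - best.tss
    else:
        signed = best.tss - position
    return best, signed


def annotate_peak(
    peak: Peak,
    genes: list[GeneModel],
    promoter_window: int = 1000,
) -> tuple[AnnotationCategory, str | None, int | None]:
    """Assign one genomic-region category to a peak.

    Promoter: any TSS within ``promoter_window`` bp of any peak base.
    Otherwise, a peak overlapping a gene is categorized by priority
    utr5 > utr3 > exon > intron; peaks touching no gene and more than
    ``promoter_window`` bp from every TSS are distal intergenic.
    """
    iv = peak.interval
    gene, signed_dist = closest_tss(iv.center, iv.chrom, genes)
    closest = gene.gene_id if gene is not None else None

    same_chrom = [g for g in genes if g.interval.chrom == iv.chrom]
    if not same_chrom:
        return AnnotationCategory.DISTAL_INTERGENIC, closest, signed_dist

    for g in same_chrom:
        if _tss_distance_to_interval(g.tss, iv) <= promoter_window:
            return AnnotationCategory.PROMOTER, closest, signed_dist

    best_cat: AnnotationCategory | None = None
    priority = {c: i for i, c in enumerate(ANNOTATION_PRIORITY)}
    for g in same_chrom:
        if not iv.overlaps(g.interval):
            continue
        if any(iv.overlaps(u) for u in g.utr5):
            cat = AnnotationCategory.UTR5
        elif any(iv.overlaps(u) for u in g.utr3):
            cat = AnnotationCategory.UTR3
        elif any(iv.overlaps(e) for e in g.exons):
            cat = AnnotationCategory.EXON
        else:
            cat = AnnotationCategory.INTRON
        if best_cat is None or priority[cat] < priority[best_cat]:
            best_cat = cat
    if best_cat is None:
        best_cat = AnnotationCategory.DISTAL_INTERGENIC
    return best_cat, closest, signed_dist


def annotate_peaks(
    peaks: list[Peak], genes: list[GeneModel], promoter_window: int = 1000
) -> list[Peak]:
    """Annotate peaks in place (category, closest gene, TSS distance)."""
    for p in peaks:
        cat, gene, dist = annotate_peak(p, genes, promoter_window)
        p.annotation, p.closest_gene, p.dist_to_tss = cat, gene, dist
    return peaks


# ---------------------------------------------------------------------------
# GC content


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence: (G+C)/(A+C+G+T), ambiguous bases excluded."""
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def gc_content_interval(
    interval: GenomicInterval, chrom_sequences: dict[str, str]
) -> float:
    """GC fraction of an interval against per-chromosome sequences."""
    if interval.chrom not in chrom_sequences:
        raise KeyError(f"no sequence for chromosome {interval.chrom}")
    seq = chrom_sequences[interval.chrom]
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval} outside sequence bounds ({len(seq)} bp)"
        )
    return gc_content(seq[interval.start : interval.end])
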