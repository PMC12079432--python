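"""Super-enhancer identification from ATAC signal, ROSE-style.

TSS-proximal peaks (1 kb upstream to 100 bp downstream of any TSS,
strand-relative) are excluded; remaining peaks separated by less than the
stitch gap (12.5 kb) are merged; each stitched region is scored by
depth-normalized treatment coverage minus depth-normalized input-DNA
background over its constituent peaks; regions above the inflection of
the ranked-signal curve are super-enhancers.  Cross-condition categories
(shared / A-only / B-only) come from >= 1 bp overlap of called SEs, and
expression integration labels each SE-assigned gene by its differential
status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GeneModel, GenomicInterval, Peak, closest_tss
from .elbow import RankCurve, find_inflection
from .footprint import CutSiteTrack
from .norm import DifferentialResult


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    constituent_peaks: list[Peak]
    condition: str = ""

    @property
    def constituent_peak_ids(self) -> list[str]:
        return [p.id for p in self.constituent_peaks]


@dataclass
class SuperEnhancerCall:
    region: StitchedRegion
    signal: float
    rank: int
    is_se: bool
    assigned_gene: str | None = None
    category: str | None = None  # shared | a_only | b_only


@dataclass
class SEExpressionRecord:
    assigned_gene: str
    category: str
    mean_abundance: float
    log2fc: float
    expression_class: str  # up | down | unchanged


@dataclass
class VennCounts:
    a_only: int
    b_only: int
    shared: int

    @property
    def total_units(self) -> int:
        return self.a_only + self.b_only + self.shared


def exclude_tss_proximal(
    peaks: list[Peak],
    genes: list[GeneModel],
    upstream: int = 1000,
    downstream: int = 100,
) -> list[Peak]:
    """Drop peaks overlapping any strand-relative TSS exclusion window.

    The window spans ``upstream`` bp before to ``downstream`` bp after the
    TSS in the gene's orientation, inclusive of both window ends.
    """
    windows: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream + 1
        else:
            lo, hi = g.tss - downstream, g.tss + upstream + 1
        windows.setdefault(g.interval.chrom, []).append((max(0, lo), hi))
    kept = []
    for p in peaks:
        iv = p.interval
        hit = any(
            iv.start < hi and lo < iv.end
            for lo, hi in windows.get(iv.chrom, ())
        )
        if not hit:
            kept.append(p)
    return kept


def stitch(
    peaks: list[Peak], gap: int = 12500, condition: str = ""
) -> list[StitchedRegion]:
    """Merge same-chromosome peaks separated by less than ``gap`` bp.

    The gap is next.start - prev.end with a strict inequality: a 12,499 bp
    gap stitches, 12,500 does not.
    """
    ordered = sorted(
        peaks, key=lambda p: (p.interval.chrom, p.interval.start)
    )
    regions: list[StitchedRegion] = []
    current: list[Peak] = []
    for p in ordered:
        if (
            current
            and p.interval.chrom == current[-1].interval.chrom
            and p.interval.start - max(q.interval.end for q in current) < gap
        ):
            current.append(p)
        else:
            if current:
                regions.append(_region_from(current, condition))
            current = [p]
    if current:
        regions.append(_region_from(current, condition))
    return regions


def _region_from(peaks: list[Peak], condition: str) -> StitchedRegion:
    chrom = peaks[0].interval.chrom
    start = min(p.interval.start for p in peaks)
    end = max(p.interval.end for p in peaks)
    return StitchedRegion(
        GenomicInterval(chrom, start, end), list(peaks), condition
    )


def region_signal(
    region: StitchedRegion,
    treatment: CutSiteTrack,
    background: CutSiteTrack,
) -> float:
    """Background-subtracted, depth-normalized ATAC signal of a region.

    Treatment and background coverage are summed over the constituent peak
    intervals, each scaled to per-million of its own track total, then
    subtracted with a floor at 0.
    """
    t_total, b_total = treatment.total, background.total
    t_sum = b_sum = 0.0
    for p in region.constituent_peaks:
        iv = p.interval
        if iv.chrom not in treatment.arrays or iv.chrom not in background.arrays:
            raise KeyError(f"region chromosome {iv.chrom} missing from track")
        if iv.end > treatment.arrays[iv.chrom].size:
            raise ValueError(f"region {iv} outside treatment track bounds")
        t_sum += float(treatment.arrays[iv.chrom][iv.start : iv.end].sum())
        b_sum += float(background.arrays[iv.chrom][iv.start : iv.end].sum())
    t_norm = t_sum * 1e6 / t_total if t_total > 0 else 0.0
    b_norm = b_sum * 1e6 / b_total if b_total > 0 else 0.0
    return max(0.0, t_norm - b_norm)


def assign_closest_gene(
    region: StitchedRegion, genes: list[GeneModel]
) -> str | None:
    """Gene whose TSS is nearest the region midpoint (ties: smaller id)."""
    if not genes:
        raise ValueError("gene list is empty")
    gene, _ = closest_tss(region.interval.center, region.interval.chrom, genes)
    return gene.gene_id if gene is not None else None


def call_superenhancers(
    peaks: list[Peak],
    genes: list[GeneModel],
    treatment: CutSiteTrack,
    background: CutSiteTrack,
    condition: str = "",
    stitch_gap: int = 12500,
    tss_upstream: int = 1000,
    tss_downstream: int = 100,
) -> tuple[list[SuperEnhancerCall], RankCurve]:
    """Full SE pipeline for one condition.

    Returns calls sorted by descending signal (rank 1 = strongest) and
    the ranked-signal curve with its inflection threshold.
    """
    distal = exclude_tss_proximal(peaks, genes, tss_upstream, tss_downstream)
    regions = stitch(distal, gap=stitch_gap, condition=condition)
    signals = np.array(
        [region_signal(r, treatment, background) for r in regions]
    )
    curve = find_inflection(signals)
    order = np.argsort(-signals, kind="stable")
    calls = []
    for rank, i in enumerate(order, start=1):
        calls.append(
            SuperEnhancerCall(
                region=regions[i],
                signal=float(signals[i]),
                rank=rank,
                is_se=bool(signals[i] > curve.threshold_signal),
                assigned_gene=assign_closest_gene(regions[i], genes),
            )
        )
    return calls, curve


def categorize_ses(
    calls_a: list[SuperEnhancerCall], calls_b: list[SuperEnhancerCall]
) -> tuple[list[SuperEnhancerCall], list[SuperEnhancerCall], VennCounts]:
    """Label SEs shared / a_only / b_only by >= 1 bp cross-condition overlap.

    Venn counts treat overlapping cross-condition SEs as merged units so
    that a_only + b_only + shared partitions the SE universe.
    """
    ses_a = [c for c in calls_a if c.is_se]
    ses_b = [c for c in calls_b if c.is_se]
    for c in ses_a:
        c.category = (
            "shared"
            if any(c.region.interval.overlaps(d.region.interval) for d in ses_b)
            else "a_only"
        )
    for d in ses_b:
        d.category = (
            "shared"
            if any(d.region.interval.overlaps(c.region.interval) for c in ses_a)
            else "b_only"
        )
    # merged cross-condition units
    tagged = [(c.region.interval, "a") for c in ses_a] + [
        (d.region.interval, "b") for d in ses_b
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start))
    counts = {"a_only": 0, "b_only": 0, "shared": 0}
    cur_chrom, cur_end, cur_tags = None, -1, set()
    for iv, tag in tagged:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
            cur_tags.add(tag)
        else:
            if cur_tags:
                counts[_unit_label(cur_tags)] += 1
            cur_chrom, cur_end, cur_tags = iv.chrom, iv.end, {tag}
    if cur_tags:
        counts[_unit_label(cur_tags)] += 1
    venn = VennCounts(counts["a_only"], counts["b_only"], counts["shared"])
    return calls_a, calls_b, venn


def _unit_label(tags: set[str]) -> str:
    if tags == {"a"}:
        return "a_only"
    if tags == {"b"}:
        return "b_only"
    return "shared"


@dataclass
class ExpressionIntegration:
    records: list[SEExpressionRecord]
    tallies: dict[str, dict[str, int]]  # category -> class -> count
    missing_genes: list[str] = field(default_factory=list)
    abundance_comparison: dict[str, float] | None = None


def integrate_expression(
    calls: list[SuperEnhancerCall],
    de: list[DifferentialResult],
    abundance: dict[str, float],
) -> ExpressionIntegration:
    """Label SE-assigned genes by differential-expression status.

    ``abundance`` maps gene -> mean log2(TPM+1) or log2(CPM+1).  Also
    compares the abundance of SE-assigned genes against regular-enhancer
    genes and all remaining genes with rank-sum tests.
    """
    de_by_id = {r.feature_id: r for r in de}
    records, missing = [], []
    tallies: dict[str, dict[str, int]] = {}
    for c in calls:
        if not c.is_se:
            continue
        gene = c.assigned_gene
        cat = c.category or "uncategorized"
        if gene is None or gene not in de_by_id:
            missing.append(gene)
            continue
        r = de_by_id[gene]
        klass = {"up": "up", "down": "down"}.get(r.status, "unchanged")
        records.append(
            SEExpressionRecord(
                assigned_gene=gene,
                category=cat,
                mean_abundance=float(abundance.get(gene, np.nan)),
                log2fc=r.log2fc,
                expression_class=klass,
            )
        )
        tallies.setdefault(cat, {"up": 0, "down": 0, "unchanged": 0})
        tallies[cat][klass] += 1

    se_genes = {c.assigned_gene for c in calls if c.is_se and c.assigned_gene}
    re_genes = {
        c.assigned_gene for c in calls if not c.is_se and c.assigned_gene
    } - se_genes
    other = set(abundance) - se_genes - re_genes
    comparison = None
    se_ab = [abundance[g] for g in se_genes if g in abundance]
    re_ab = [abundance[g] for g in re_genes if g in abundance]
    other_ab = [abundance[g] for g in other]
    if se_ab and other_ab:
        comparison = {
            "se_mean": float(np.mean(se_ab)),
            "regular_mean": float(np.mean(re_ab)) if re_ab else float("nan"),
            "other_mean": float(np.mean(other_ab)),
            "p_se_vs_other": float(
                stats.mannwhitneyu(se_ab, other_ab, alternative="greater")[1]
            ),
        }
        if re_ab:
            comparison["p_se_vs_regular"] = float(
                stats.mannwhitneyu(se_ab, re_ab, alternative="greater")[1]
            )
    return ExpressionIntegration(records, tallies, missing, comparison)
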