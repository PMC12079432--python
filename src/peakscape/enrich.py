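"""Over-representation and preranked gene-set enrichment tests.

ORA is the upper-tail hypergeometric test of a hit list against gene (or
region) sets drawn from a common universe, BH-adjusted across sets.
Preranked GSEA computes the weighted Kolmogorov–Smirnov-like running-sum
enrichment score over a descending-ranked gene list, with significance
from gene-label permutations and NES normalized by the mean magnitude of
same-signed permuted scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomicInterval
from .footprint import MotifOccurrence
from .norm import bh_adjust


@dataclass
class ORAResult:
    set_id: str
    overlap: int  # k
    set_size: int  # K (within universe)
    hits_size: int  # n
    universe: int  # N
    p: float
    adj_p: float
    fold_enrichment: float


@dataclass
class GSEAResult:
    set_id: str
    es: float
    nes: float
    p: float
    n_perm: int


def ora_test(
    hits: set[str],
    universe: set[str],
    sets: dict[str, set[str]],
) -> list[ORAResult]:
    """Hypergeometric over-representation of ``hits`` in each set.

    Sets are intersected with the universe first; sets disjoint from the
    universe are skipped with a warning.  p = P(X >= k) for X ~
    Hypergeom(N, K, n); BH adjustment across tested sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits:
        raise ValueError("empty hit list")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    n_total = len(universe)
    n_hits = len(hits)
    rows = []
    for set_id, members in sets.items():
        in_universe = members & universe
        if not in_universe:
            warnings.warn(f"set {set_id} disjoint from universe; skipped")
            continue
        k_set = len(in_universe)
        k = len(in_universe & hits)
        p = float(stats.hypergeom.sf(k - 1, n_total, k_set, n_hits))
        fold = (k / n_hits) / (k_set / n_total) if k_set else float("nan")
        rows.append((set_id, k, k_set, p, fold))
    if not rows:
        return []
    adj = bh_adjust([r[3] for r in rows])
    return [
        ORAResult(set_id, k, k_set, n_hits, n_total, p, float(a), fold)
        for (set_id, k, k_set, p, fold), a in zip(rows, adj)
    ]


def motif_enrichment_in_regions(
    target_regions: list[GenomicInterval],
    background_regions: list[GenomicInterval],
    occurrences: dict[str, list[MotifOccurrence]],
) -> list[ORAResult]:
    """Region-level motif over-representation.

    A region "contains" a motif when at least one occurrence overlaps it;
    the hypergeometric universe is the background region list (which must
    contain the targets).  Motifs with zero occurrences are skipped.
    """
    if not target_regions:
        raise ValueError("empty target region list")
    region_key = {
        (iv.chrom, iv.start, iv.end): i
        for i, iv in enumerate(background_regions)
    }
    for iv in target_regions:
        if (iv.chrom, iv.start, iv.end) not in region_key:
            raise ValueError(f"target region {iv} not in background universe")
    universe = {f"region{i}" for i in range(len(background_regions))}
    hits = {
        f"region{region_key[(iv.chrom, iv.start, iv.end)]}"
        for iv in target_regions
    }
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(background_regions):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    sets = {}
    for motif_id, occs in occurrences.items():
        if not occs:
            continue
        containing = set()
        for occ in occs:
            p = occ.position
            for start, end, i in by_chrom.get(p.chrom, ()):
                if p.start < end and start < p.end:
                    containing.add(f"region{i}")
        if containing:
            sets[motif_id] = containing
    return ora_test(hits, universe, sets)


def enrichment_score(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score on a descending-ranked list.

    Hits advance the running sum by |score|^weight (normalized over hits);
    misses retreat by 1/(N-K).  ES is the maximum-magnitude excursion.
    """
    n = len(ranked_genes)
    hit = np.fromiter(
        (g in gene_set for g in ranked_genes), dtype=bool, count=n
    )
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if k == n:
        raise ValueError("gene set covers the whole ranked list (no misses)")
    w = np.abs(np.asarray(scores, dtype=float)) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit scores are zero: fall back to unweighted steps
        hit_w = hit.astype(float)
        denom = float(k)
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hit) / (n - k)
    running = p_hit - p_miss
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_preranked(
    ranked: list[tuple[str, float]],
    gene_set: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """Preranked GSEA with gene-label permutation significance.

    ``ranked`` is a (gene, score) list sorted by descending score.  The
    permutation null redraws the gene set as random same-size label sets;
    p is one-sided among permutations with the observed ES sign
    (floor 1/(n_perm+1)); NES = ES / mean |same-signed permuted ES|.
    """
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    overlap = set(genes) & gene_set
    es, _ = enrichment_score(genes, scores, overlap, weight=weight)

    rng = np.random.default_rng(seed)
    n, k = len(genes), len(overlap)
    w = np.abs(scores) ** weight
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        perm_es[i] = _es_from_positions(idx, w, n, k)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size == 0:
        p = 1.0 / (n_perm + 1)
        nes = float("nan")
    else:
        exceed = int(np.sum(np.abs(same_sign) >= abs(es)))
        p = (exceed + 1) / (same_sign.size + 1)
        nes = float(es / np.mean(np.abs(same_sign)))
    return GSEAResult(set_id="", es=es, nes=nes, p=float(p), n_perm=n_perm)


def _es_from_positions(
    positions: np.ndarray, w: np.ndarray, n: int, k: int
) -> float:
    """ES for a hit-position set, evaluated at the hit points only.

    The running sum is piecewise linear between hits with a constant miss
    slope, so its extrema occur immediately at or before hit positions.
    """
    pos = np.sort(positions)
    hw = w[pos]
    denom = hw.sum()
    if denom == 0:
        hw = np.ones(k)
        denom = float(k)
    cum_hit = np.cumsum(hw) / denom
    miss_step = 1.0 / (n - k)
    # misses before each hit position: pos[i] - i
    miss_before = (pos - np.arange(k)) * miss_step
    at_hit = cum_hit - miss_before
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - miss_before
    # also the final point (all misses consumed) returns to 0; extremes
    # are covered by at_hit (max candidates) and before_hit (min candidates)
    candidates = np.concatenate((at_hit, before_hit))
    return float(candidates[np.argmax(np.abs(candidates))])
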