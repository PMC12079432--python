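"""Two-condition synthetic ATAC/RNA datasets with planted ground truth.

The generator emulates the statistical structure of a two-condition
(A = resting, B = stimulated), three-replicate ATAC-seq + RNA-seq
experiment on a small synthetic genome:

* negative-binomial peak counts with library-size and GC effects;
* planted condition-B accessibility shifts at motif-bearing peaks;
* planted clusters of >= 3 high-signal peaks within stitching distance
  (super-enhancers), some condition-specific;
* per-base cut-site tracks with core protection at bound motif
  occurrences (footprints);
* input-DNA background coverage (Poisson around a constant rate);
* RNA counts with planted differential expression coupled to promoter
  accessibility and to condition-specific super-enhancers.

Everything is a pure function of the seed: the same configuration yields
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .core import CountMatrix, GeneModel, GenomicInterval, Peak
from .footprint import CutSiteTrack, MotifOccurrence


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 9_000_000
    n_genes: int = 600
    n_peaks: int = 2000  # regular (non-cluster) peaks, incl. one per gene
    n_se_clusters: tuple[int, int, int] = (10, 5, 5)  # shared, A-only, B-only
    peaks_per_cluster: int = 5
    cluster_gap_range: tuple[int, int] = (800, 2200)
    peak_width_range: tuple[int, int] = (450, 700)
    unit_gap_range: tuple[int, int] = (12600, 15000)
    gene_length_range: tuple[int, int] = (3000, 8000)
    n_motifs: int = 50
    motif_members: int = 200
    motif_width: int = 10
    motif_shift_effects: dict[str, float] = field(
        default_factory=lambda: {"motif_000": 1.0, "motif_001": -1.0}
    )
    bound_motif: str = "motif_000"
    footprint_protection: float = 0.5
    nb_dispersion: float = 0.1
    base_count_mean: float = 100.0
    library_sizes: tuple[float, ...] = (1.0, 1.1, 0.9, 1.05, 0.95, 1.02)
    gc_effect_strength: float = 1.0
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    promoter_shift: float = 1.5
    concordance: float = 0.8  # P(promoter DA direction matches DE direction)
    se_coupling: float = 0.8  # P(B-only SE target gene is upregulated)
    peak_cut_rate: float = 0.2  # cuts per bp inside a regular peak
    cluster_boost: float = 10.0
    background_rate_frac: float = 0.5  # of peak_cut_rate
    background_bin: int = 200

    def __post_init__(self) -> None:
        if self.peaks_per_cluster < 3:
            raise ValueError("SE clusters need >= 3 peaks")
        if not 0 <= self.footprint_protection <= 1:
            raise ValueError("footprint_protection must lie in [0, 1]")
        if self.n_genes > self.n_peaks:
            raise ValueError("need n_peaks >= n_genes (one promoter peak each)")


@dataclass
class SyntheticTruth:
    planted_se_regions: list[tuple[GenomicInterval, str]]
    planted_da_peaks: dict[str, float]  # peak id -> true log2FC (B over A)
    planted_motif_shifts: dict[str, float]
    planted_de_genes: dict[str, float]  # gene id -> true log2FC
    bound_motif_occurrences: list[GenomicInterval]
    cluster_target_genes: dict[str, str]  # category:index -> gene id


@dataclass
class Dataset:
    """In-memory view of one simulated experiment."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]  # consensus universe, genome-sorted, gc populated
    peaks_a: list[str]  # peak ids present in condition A
    peaks_b: list[str]
    atac_counts: CountMatrix
    rna_counts: CountMatrix
    membership: dict[str, list[str]]
    occurrences: dict[str, list[MotifOccurrence]]
    cut_tracks: dict[str, CutSiteTrack]  # condition -> track
    background: CutSiteTrack
    gene_sets: dict[str, set[str]]


# ---------------------------------------------------------------------------
# layout


def _layout(config: SyntheticConfig, rng: np.random.Generator):
    """Place distal peaks, genes and SE clusters along the genome."""
    n_distal = config.n_peaks - config.n_genes
    cluster_units = []
    for cat, n in zip(("shared", "a_only", "b_only"), config.n_se_clusters):
        cluster_units += [("cluster", cat, i) for i in range(n)]
    # each cluster carries its own target gene, drawn from the gene budget
    n_free_genes = config.n_genes - len(cluster_units)
    if n_free_genes < 0:
        raise ValueError("n_genes must cover one target gene per SE cluster")
    units: list[tuple] = [("distal",)] * n_distal
    units += [("gene", i) for i in range(n_free_genes)]
    units += cluster_units
    rng.shuffle(units)

    peaks: list[dict] = []  # raw peak dicts before sorting/id assignment
    genes: list[GeneModel] = []
    clusters: list[dict] = []
    chrom_idx, pos = 0, 1000

    def chrom() -> str:
        return f"chr{chrom_idx + 1}"

    def advance_or_jump(span: int) -> int:
        nonlocal chrom_idx, pos
        if pos + span > config.chrom_length - 1000:
            chrom_idx += 1
            pos = 1000
            if chrom_idx >= config.n_chroms:
                raise ValueError(
                    "infeasible geometry: units exceed total genome length"
                )
        return pos

    pw = lambda: int(rng.integers(*config.peak_width_range))
    gap = lambda: int(rng.integers(*config.unit_gap_range))

    gene_counter = 0
    for unit in units:
        if unit[0] == "distal":
            w = pw()
            start = advance_or_jump(w)
            peaks.append(
                {"chrom": chrom(), "start": start, "end": start + w,
                 "kind": "distal", "gene": None, "cluster": None}
            )
            pos = start + w + gap()
        elif unit[0] == "gene":
            g, promoter, consumed = _make_gene(
                config, rng, chrom(), advance_or_jump(12000), gene_counter
            )
            gene_counter += 1
            genes.append(g)
            peaks.append(promoter)
            pos = consumed + gap()
        else:  # cluster followed by its target gene
            _, cat, _ = unit
            w_needed = config.peaks_per_cluster * 700 + (
                config.peaks_per_cluster - 1
            ) * config.cluster_gap_range[1] + 16000 + 12000
            start = advance_or_jump(w_needed)
            cluster_peaks = []
            p = start
            for _k in range(config.peaks_per_cluster):
                w = pw()
                cluster_peaks.append(
                    {"chrom": chrom(), "start": p, "end": p + w,
                     "kind": "cluster", "gene": None, "cluster": cat}
                )
                p += w + int(rng.integers(*config.cluster_gap_range))
            region = GenomicInterval(
                chrom(), cluster_peaks[0]["start"], cluster_peaks[-1]["end"]
            )
            # target gene downstream, outside stitching distance
            gpos = cluster_peaks[-1]["end"] + int(rng.integers(13000, 15000))
            g, promoter, consumed = _make_gene(
                config, rng, chrom(), gpos, gene_counter, extra=True
            )
            gene_counter += 1
            genes.append(g)
            peaks.append(promoter)
            peaks.extend(cluster_peaks)
            clusters.append(
                {"category": cat, "region": region, "gene": g.gene_id,
                 "peak_idx": None}
            )
            pos = consumed + gap()
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    return peaks, genes, clusters, sizes


def _make_gene(config, rng, chrom, start, counter, extra=False):
    """One gene with TSS-centered promoter peak, exons and UTRs."""
    glen = int(rng.integers(*config.gene_length_range))
    strand = "+" if rng.random() < 0.5 else "-"
    w = int(rng.integers(*config.peak_width_range))
    gstart = start + w  # leave room for the promoter peak upstream
    gend = gstart + glen
    iv = GenomicInterval(chrom, gstart, gend, strand)
    tss = gstart if strand == "+" else gend - 1
    exlen = min(500, glen // 4)
    exons = [
        GenomicInterval(chrom, gstart, gstart + exlen, strand),
        GenomicInterval(
            chrom, gstart + glen // 2, gstart + glen // 2 + exlen, strand
        ),
        GenomicInterval(chrom, gend - exlen, gend, strand),
    ]
    if strand == "+":
        utr5 = [GenomicInterval(chrom, gstart, gstart + 150, strand)]
        utr3 = [GenomicInterval(chrom, gend - 150, gend, strand)]
    else:
        utr5 = [GenomicInterval(chrom, gend - 150, gend, strand)]
        utr3 = [GenomicInterval(chrom, gstart, gstart + 150, strand)]
    gene = GeneModel(
        gene_id=f"gene_{counter:04d}",
        symbol=f"GENE{counter:04d}",
        interval=iv,
        exons=exons,
        utr5=utr5,
        utr3=utr3,
    )
    promoter = {
        "chrom": chrom, "start": tss - w // 2, "end": tss - w // 2 + w,
        "kind": "promoter", "gene": gene.gene_id, "cluster": None,
    }
    consumed = max(gend, promoter["end"])
    return gene, promoter, consumed


# ---------------------------------------------------------------------------
# counts


def negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws in mean–dispersion parameterization (var = m + a m^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_count_matrix(
    n_features: int = 2000,
    n_per_group: int = 3,
    planted_log2fc: float = 3.0,
    planted_fraction: float = 0.05,
    dispersion: float = 0.1,
    base_mean: float = 100.0,
    seed: int = 0,
) -> tuple[CountMatrix, dict[str, float]]:
    """Standalone two-group NB count matrix with planted fold changes.

    Returns the matrix and a truth map feature -> planted log2FC (nonzero
    entries only, positive shifts applied in group B).
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(base_mean), 0.6, size=n_features)
    n_planted = int(round(planted_fraction * n_features))
    planted = rng.choice(n_features, size=n_planted, replace=False)
    fc = np.zeros(n_features)
    fc[planted] = planted_log2fc
    libs = rng.uniform(0.9, 1.1, size=2 * n_per_group)
    mean_a = mu[:, None] * libs[None, :n_per_group]
    mean_b = (mu * 2.0**fc)[:, None] * libs[None, n_per_group:]
    counts = np.concatenate(
        [
            negative_binomial(rng, mean_a, dispersion),
            negative_binomial(rng, mean_b, dispersion),
        ],
        axis=1,
    )
    feature_ids = [f"feat_{i:05d}" for i in range(n_features)]
    sample_ids = [f"A_{i+1}" for i in range(n_per_group)] + [
        f"B_{i+1}" for i in range(n_per_group)
    ]
    groups = {s: s.split("_")[0] for s in sample_ids}
    truth = {feature_ids[i]: float(fc[i]) for i in planted}
    return CountMatrix(feature_ids, sample_ids, counts, groups), truth


# ---------------------------------------------------------------------------
# main generator


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[Dataset, SyntheticTruth]:
    """Simulate one experiment in memory.  Deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    raw_peaks, genes, clusters, chrom_sizes = _layout(config, rng)

    order = sorted(
        range(len(raw_peaks)),
        key=lambda i: (raw_peaks[i]["chrom"], raw_peaks[i]["start"]),
    )
    raw_peaks = [raw_peaks[i] for i in order]
    n_pk = len(raw_peaks)
    gc = rng.beta(10, 10, size=n_pk)
    peak_ids = [f"peak_{i:05d}" for i in range(n_pk)]
    gene_by_id = {g.gene_id: g for g in genes}

    # motif membership, GC-biased per motif
    motif_ids = [f"motif_{j:03d}" for j in range(config.n_motifs)]
    membership: dict[str, list[str]] = {}
    for m in motif_ids:
        b = rng.normal(0, 2)
        w = np.exp(b * (gc - 0.5))
        p = w / w.sum()
        size = min(config.motif_members, n_pk)
        members = rng.choice(n_pk, size=size, replace=False, p=p)
        membership[m] = [peak_ids[i] for i in np.sort(members)]

    # planted condition-B log2 shifts per peak
    shift_b = np.zeros(n_pk)
    peak_index = {pid: i for i, pid in enumerate(peak_ids)}
    motif_shifts = {m: 0.0 for m in motif_ids}
    motif_shifts.update(
        {m: s for m, s in config.motif_shift_effects.items()
         if m in motif_shifts}
    )
    for m, s in motif_shifts.items():
        if s == 0:
            continue
        for pid in membership[m]:
            shift_b[peak_index[pid]] += s

    # differential expression truth, coupled to SE categories
    de_genes: dict[str, float] = {}
    for cl in clusters:
        if cl["category"] == "b_only":
            sign = 1.0 if rng.random() < config.se_coupling else -1.0
        elif cl["category"] == "a_only":
            sign = -1.0 if rng.random() < config.se_coupling else 1.0
        else:
            continue
        de_genes[cl["gene"]] = sign * config.de_log2fc
    n_de = int(round(config.de_fraction * config.n_genes))
    free = [g.gene_id for g in genes if g.gene_id not in de_genes]
    extra = max(0, n_de - len(de_genes))
    for gid in rng.choice(len(free), size=min(extra, len(free)),
                          replace=False):
        de_genes[free[gid]] = (
            config.de_log2fc if rng.random() < 0.5 else -config.de_log2fc
        )

    # promoter accessibility coupled to DE direction
    promoter_peak_of: dict[str, str] = {}
    for i, rp in enumerate(raw_peaks):
        if rp["kind"] == "promoter":
            promoter_peak_of[rp["gene"]] = peak_ids[i]
    for gid, fc in de_genes.items():
        sign = np.sign(fc)
        if rng.random() >= config.concordance:
            sign = -sign
        shift_b[peak_index[promoter_peak_of[gid]]] += (
            sign * config.promoter_shift
        )

    # condition multipliers (cluster activity) and ATAC counts
    mult_a = np.ones(n_pk)
    mult_b = np.ones(n_pk)
    for i, rp in enumerate(raw_peaks):
        if rp["kind"] == "cluster":
            if rp["cluster"] in ("shared", "a_only"):
                mult_a[i] = config.cluster_boost
            if rp["cluster"] in ("shared", "b_only"):
                mult_b[i] = config.cluster_boost
    mult_b = mult_b * 2.0**shift_b

    mu = rng.lognormal(np.log(config.base_count_mean), 0.6, size=n_pk)
    gc_fac = 2.0 ** (config.gc_effect_strength * (gc - 0.5))
    libs = np.asarray(config.library_sizes, dtype=float)
    n_rep = libs.size // 2
    mean_a = (mu * mult_a * gc_fac)[:, None] * libs[None, :n_rep]
    mean_b = (mu * mult_b * gc_fac)[:, None] * libs[None, n_rep:]
    atac = np.concatenate(
        [
            negative_binomial(rng, mean_a, config.nb_dispersion),
            negative_binomial(rng, mean_b, config.nb_dispersion),
        ],
        axis=1,
    )
    sample_ids = [f"A_{i+1}" for i in range(n_rep)] + [
        f"B_{i+1}" for i in range(n_rep)
    ]
    groups = {s: s.split("_")[0] for s in sample_ids}
    atac_counts = CountMatrix(list(peak_ids), sample_ids, atac, groups)

    # RNA counts; SE target genes carry a higher baseline (+2 log2),
    # emulating the elevated expression of SE-associated genes
    mu_g = rng.lognormal(np.log(200.0), 1.0, size=config.n_genes)
    se_targets = {cl["gene"] for cl in clusters}
    for gi, g in enumerate(genes):
        if g.gene_id in se_targets:
            mu_g[gi] *= 4.0
    fc_g = np.array(
        [de_genes.get(g.gene_id, 0.0) for g in genes], dtype=float
    )
    rmean_a = mu_g[:, None] * libs[None, :n_rep]
    rmean_b = (mu_g * 2.0**fc_g)[:, None] * libs[None, n_rep:]
    rna = np.concatenate(
        [
            negative_binomial(rng, rmean_a, config.nb_dispersion),
            negative_binomial(rng, rmean_b, config.nb_dispersion),
        ],
        axis=1,
    )
    rna_counts = CountMatrix(
        [g.gene_id for g in genes], sample_ids, rna, dict(groups)
    )

    # motif occurrences at member-peak centers
    starts = np.array([rp["start"] for rp in raw_peaks])
    ends = np.array([rp["end"] for rp in raw_peaks])
    centers = (starts + ends) // 2
    occurrences: dict[str, list[MotifOccurrence]] = {}
    for m in motif_ids:
        occs = []
        for pid in membership[m]:
            i = peak_index[pid]
            s = int(centers[i] - config.motif_width // 2)
            strand = "+" if rng.random() < 0.5 else "-"
            occs.append(
                MotifOccurrence(
                    m,
                    GenomicInterval(
                        raw_peaks[i]["chrom"], s, s + config.motif_width,
                        strand,
                    ),
                )
            )
        occurrences[m] = occs

    bound_cores: dict[str, list[tuple[int, int]]] = {}
    bound_ivs: list[GenomicInterval] = []
    if config.bound_motif in occurrences:
        for occ in occurrences[config.bound_motif]:
            bound_cores.setdefault(occ.position.chrom, []).append(
                (occ.position.start, occ.position.end)
            )
            bound_ivs.append(occ.position)

    # cut-site tracks: Poisson per base inside peaks, protected cores in B
    peaks_a_mask = np.array(
        [rp["cluster"] != "b_only" for rp in raw_peaks]
    )
    peaks_b_mask = np.array(
        [rp["cluster"] != "a_only" for rp in raw_peaks]
    )
    cut_tracks = {}
    for cond, mask, mult, protect in (
        ("A", peaks_a_mask, mult_a, False),
        ("B", peaks_b_mask, mult_b / 2.0**shift_b, True),
    ):
        arrays = {
            c: np.zeros(n, dtype=np.float32) for c, n in chrom_sizes.items()
        }
        for i in np.flatnonzero(mask):
            rp = raw_peaks[i]
            base = config.peak_cut_rate * (
                config.cluster_boost if mult[i] > 1.5 else 1.0
            )
            rate = np.full(rp["end"] - rp["start"], base)
            if protect and rp["chrom"] in bound_cores:
                for cs, ce in bound_cores[rp["chrom"]]:
                    if cs >= rp["start"] and ce <= rp["end"]:
                        rate[cs - rp["start"] : ce - rp["start"]] *= (
                            1.0 - config.footprint_protection
                        )
            arrays[rp["chrom"]][rp["start"] : rp["end"]] = rng.poisson(rate)
        cut_tracks[cond] = CutSiteTrack(arrays)

    # background input-DNA coverage: Poisson around a constant per-bp rate
    bg_rate = config.background_rate_frac * config.peak_cut_rate
    bin_w = config.background_bin
    bg_arrays = {}
    for c, n in chrom_sizes.items():
        n_bins = n // bin_w
        vals = rng.poisson(bg_rate * bin_w, size=n_bins) / bin_w
        arr = np.zeros(n, dtype=np.float32)
        arr[: n_bins * bin_w] = np.repeat(vals, bin_w)
        bg_arrays[c] = arr
    background = CutSiteTrack(bg_arrays)

    # gene sets: one per motif; shifted motifs draw half their targets
    # from DE genes of the matching direction
    all_gene_ids = [g.gene_id for g in genes]
    gene_sets: dict[str, set[str]] = {}
    for m in motif_ids:
        size = int(rng.integers(30, 80))
        s = motif_shifts[m]
        if s != 0:
            want = [g for g, f in de_genes.items() if np.sign(f) == np.sign(s)]
            n_sig = min(len(want), size // 2)
            picked = set(
                rng.choice(want, size=n_sig, replace=False).tolist()
                if n_sig
                else []
            )
            pool = [g for g in all_gene_ids if g not in picked]
            picked |= set(
                rng.choice(pool, size=size - n_sig, replace=False).tolist()
            )
        else:
            picked = set(
                rng.choice(all_gene_ids, size=size, replace=False).tolist()
            )
        gene_sets[m] = picked

    peaks = [
        Peak(
            id=peak_ids[i],
            interval=GenomicInterval(rp["chrom"], rp["start"], rp["end"]),
            gc=float(gc[i]),
        )
        for i, rp in enumerate(raw_peaks)
    ]
    dataset = Dataset(
        chrom_sizes=chrom_sizes,
        genes=genes,
        peaks=peaks,
        peaks_a=[peak_ids[i] for i in np.flatnonzero(peaks_a_mask)],
        peaks_b=[peak_ids[i] for i in np.flatnonzero(peaks_b_mask)],
        atac_counts=atac_counts,
        rna_counts=rna_counts,
        membership=membership,
        occurrences=occurrences,
        cut_tracks=cut_tracks,
        background=background,
        gene_sets=gene_sets,
    )

    true_fc = np.log2(mult_b / mult_a)
    planted_da = {
        peak_ids[i]: float(true_fc[i])
        for i in range(n_pk)
        if abs(true_fc[i]) > 1e-9
    }
    truth = SyntheticTruth(
        planted_se_regions=[
            (cl["region"], cl["category"]) for cl in clusters
        ],
        planted_da_peaks=planted_da,
        planted_motif_shifts={
            m: s for m, s in motif_shifts.items() if s != 0
        },
        planted_de_genes=dict(de_genes),
        bound_motif_occurrences=bound_ivs,
        cluster_target_genes={
            f"{cl['category']}:{k}": cl["gene"]
            for k, cl in enumerate(clusters)
        },
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# disk round trip


def _track_records(track: CutSiteTrack):
    """Run-length encode nonzero stretches of a dense track."""
    recs = []
    for chrom in track.arrays:
        arr = np.asarray(track.arrays[chrom])
        nz = np.flatnonzero(arr)
        if nz.size == 0:
            continue
        breaks = np.flatnonzero(
            (np.diff(nz) != 1) | (np.diff(arr[nz]) != 0)
        )
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [nz.size - 1]))
        for s, e in zip(starts, ends):
            recs.append(
                psio.BedGraphRecord(
                    GenomicInterval(chrom, int(nz[s]), int(nz[e]) + 1),
                    float(arr[nz[s]]),
                )
            )
    return recs


def generate_dataset(
    config: SyntheticConfig, outdir: str | os.PathLike
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Simulate and write all files; returns paths and the planted truth."""
    dataset, truth = simulate_dataset(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "genes": "genes.tsv",
        "peaks_a": "peaks_A.bed",
        "peaks_b": "peaks_B.bed",
        "atac_counts": "atac_counts.tsv",
        "rna_counts": "rna_counts.tsv",
        "samples": "samples.tsv",
        "peak_gc": "peak_gc.tsv",
        "membership": "motif_membership.tsv",
        "occurrences": "motif_occurrences.bed",
        "cuts_a": "cuts_A.bedgraph",
        "cuts_b": "cuts_B.bedgraph",
        "background": "background.bedgraph",
        "chrom_sizes": "chrom.sizes",
        "gene_sets": "gene_sets.gmt",
        "truth_da": "truth_da_peaks.tsv",
        "truth_de": "truth_de_genes.tsv",
        "truth_se": "truth_se_regions.tsv",
        "truth_motifs": "truth_motif_shifts.tsv",
    }.items()}

    psio.write_gene_models(dataset.genes, paths["genes"])
    by_id = {p.id: p for p in dataset.peaks}
    psio.write_bed([by_id[i] for i in dataset.peaks_a], paths["peaks_a"])
    psio.write_bed([by_id[i] for i in dataset.peaks_b], paths["peaks_b"])
    psio.write_counts(
        dataset.atac_counts, paths["atac_counts"], paths["samples"],
        feature_label="peak_id",
    )
    psio.write_counts(
        dataset.rna_counts, paths["rna_counts"], feature_label="gene_id"
    )
    psio.write_peak_gc(
        {p.id: p.gc for p in dataset.peaks}, paths["peak_gc"]
    )
    psio.write_motif_membership(dataset.membership, paths["membership"])
    occ_peaks = [
        Peak(id=m, interval=o.position)
        for m in dataset.occurrences
        for o in dataset.occurrences[m]
    ]
    psio.write_bed(occ_peaks, paths["occurrences"])
    psio.write_bedgraph(
        _track_records(dataset.cut_tracks["A"]), paths["cuts_a"]
    )
    psio.write_bedgraph(
        _track_records(dataset.cut_tracks["B"]), paths["cuts_b"]
    )
    psio.write_bedgraph(
        _track_records(dataset.background), paths["background"]
    )
    psio.write_chrom_sizes(dataset.chrom_sizes, paths["chrom_sizes"])
    psio.write_gmt(dataset.gene_sets, paths["gene_sets"])

    pd.DataFrame(
        {"peak_id": list(truth.planted_da_peaks),
         "true_log2fc": list(truth.planted_da_peaks.values())}
    ).to_csv(paths["truth_da"], sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": list(truth.planted_de_genes),
         "true_log2fc": list(truth.planted_de_genes.values())}
    ).to_csv(paths["truth_de"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "category": cat}
            for iv, cat in truth.planted_se_regions
        ],
        columns=["chrom", "start", "end", "category"],
    ).to_csv(paths["truth_se"], sep="\t", index=False)
    pd.DataFrame(
        {"motif_id": list(truth.planted_motif_shifts),
         "log2_shift": list(truth.planted_motif_shifts.values())}
    ).to_csv(paths["truth_motifs"], sep="\t", index=False)
    return paths, truth


def load_dataset(outdir: str | os.PathLike) -> Dataset:
    """Read a generated dataset back from disk."""
    out = Path(outdir)
    chrom_sizes = psio.read_chrom_sizes(out / "chrom.sizes")
    genes = psio.read_gene_models(out / "genes.tsv")
    atac = psio.read_counts(out / "atac_counts.tsv", out / "samples.tsv")
    rna = psio.read_counts(out / "rna_counts.tsv", out / "samples.tsv")
    gc = psio.read_peak_gc(out / "peak_gc.tsv")
    peaks_a = psio.read_intervals(out / "peaks_A.bed", "bed")
    peaks_b = psio.read_intervals(out / "peaks_B.bed", "bed")
    by_id: dict[str, Peak] = {}
    for p in peaks_a + peaks_b:
        by_id.setdefault(p.id, p)
    peaks = sorted(
        by_id.values(), key=lambda p: (p.interval.chrom, p.interval.start)
    )
    for p in peaks:
        p.gc = gc.get(p.id)
    from .footprint import load_occurrences

    return Dataset(
        chrom_sizes=chrom_sizes,
        genes=genes,
        peaks=peaks,
        peaks_a=[p.id for p in peaks_a],
        peaks_b=[p.id for p in peaks_b],
        atac_counts=atac,
        rna_counts=rna,
        membership=psio.read_motif_membership(out / "motif_membership.tsv"),
        occurrences=load_occurrences(out / "motif_occurrences.bed"),
        cut_tracks={
            "A": CutSiteTrack.from_bedgraph(
                out / "cuts_A.bedgraph", chrom_sizes
            ),
            "B": CutSiteTrack.from_bedgraph(
                out / "cuts_B.bedgraph", chrom_sizes
            ),
        },
        background=CutSiteTrack.from_bedgraph(
            out / "background.bedgraph", chrom_sizes
        ),
        gene_sets=psio.read_gmt(out / "gene_sets.gmt"),
    )
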