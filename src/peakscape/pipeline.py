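"""End-to-end orchestration of the synthetic experiment.

``run_all`` executes simulate -> annotate -> differential -> deviation ->
footprint -> super-enhancer -> enrichment, writes every stage's tables
(each with a provenance header comment: version, seed, parameter hash)
and a machine-readable JSON run report that includes planted-truth
recovery metrics.  One global seed fans out to per-stage seeds by fixed
offsets so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import annotate_peaks, consensus_union
from .deviation import MotifPeakMembership, compute_deviations, variability_rank
from .enrich import gsea_preranked, motif_enrichment_in_regions, ora_test
from .footprint import aggregate_footprint, footprint_depth
from .norm import (
    cpm,
    differential_test,
    filter_expressed,
    promoter_da_de_correlation,
)
from .simulate import SyntheticConfig, generate_dataset, simulate_dataset
from .superenhancer import call_superenhancers, categorize_ses, integrate_expression

log = logging.getLogger("peakscape")

_SEED_OFFSETS = {"simulate": 0, "deviation": 101, "gsea": 211}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "peakscape_run"
    fc_threshold: float = 1.0
    alpha: float = 0.05
    stitch_gap: int = 12500
    tss_upstream: int = 1000
    tss_downstream: int = 100
    promoter_window: int = 1000
    min_cpm: float = 1.0
    min_samples: int = 3
    n_background: int = 50
    flank: int = 100
    n_perm: int = 1000
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        for name in (
            "fc_threshold", "alpha", "stitch_gap", "tss_upstream",
            "promoter_window", "min_cpm", "n_background", "flank", "n_perm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.synthetic = dataclasses.replace(
            self.synthetic, seed=self.seed + _SEED_OFFSETS["simulate"]
        )

    def param_hash(self) -> str:
        params = dataclasses.asdict(self)
        params.pop("outdir", None)  # a path, not a scientific parameter
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (
        f"peakscape v{__version__} seed={config.seed} "
        f"params={config.param_hash()}"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "param_hash": config.param_hash(), "stages": {}}

    log.info("stage simulate")
    try:
        _, truth = generate_dataset(config.synthetic, out / "simulated")
        dataset, _ = simulate_dataset(config.synthetic)
    except Exception as exc:  # pragma: no cover - abort contract
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    report["stages"]["simulate"] = {
        "n_peaks": len(dataset.peaks),
        "n_genes": len(dataset.genes),
        "n_motifs": len(dataset.membership),
        "n_planted_se": len(truth.planted_se_regions),
    }

    log.info("stage annotate")
    consensus = consensus_union(
        [p.interval for p in dataset.peaks if p.id in set(dataset.peaks_a)],
        [p.interval for p in dataset.peaks if p.id in set(dataset.peaks_b)],
    )
    peaks = annotate_peaks(
        dataset.peaks, dataset.genes, promoter_window=config.promoter_window
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "peak_id": p.id, "chrom": p.interval.chrom,
                    "start": p.interval.start, "end": p.interval.end,
                    "annotation": p.annotation.value,
                    "closest_gene": p.closest_gene,
                    "dist_to_tss": p.dist_to_tss,
                }
                for p in peaks
            ]
        ),
        out / "peak_annotation.tsv",
        config,
    )
    ann_counts = pd.Series(
        [p.annotation.value for p in peaks]
    ).value_counts().to_dict()
    report["stages"]["annotate"] = {
        "n_consensus_intervals": len(consensus),
        "annotation_counts": ann_counts,
    }

    log.info("stage differential")
    group_a = dataset.atac_counts.samples_in("A")
    group_b = dataset.atac_counts.samples_in("B")
    da = differential_test(
        dataset.atac_counts, group_a, group_b,
        fc_threshold=config.fc_threshold, alpha=config.alpha,
    )
    rna_kept = filter_expressed(
        dataset.rna_counts, min_cpm=config.min_cpm,
        min_samples=config.min_samples,
    )
    de = differential_test(
        rna_kept, group_a, group_b,
        fc_threshold=config.fc_threshold, alpha=config.alpha,
    )
    for name, res in (("differential_accessibility", da),
                      ("differential_expression", de)):
        _write_tsv(
            pd.DataFrame(
                [
                    {"feature_id": r.feature_id, "log2fc": r.log2fc,
                     "p": r.p, "adj_p": r.adj_p, "status": r.status}
                    for r in res
                ]
            ),
            out / f"{name}.tsv",
            config,
        )
    r_pearson, r_p, quadrants = promoter_da_de_correlation(
        da, de, peaks, fc_threshold=config.fc_threshold
    )
    n_up = sum(r.status == "up" for r in da)
    n_down = sum(r.status == "down" for r in da)
    report["stages"]["differential"] = {
        "n_peaks_tested": len(da),
        "pct_peaks_more_accessible": 100.0 * n_up / len(da),
        "pct_peaks_less_accessible": 100.0 * n_down / len(da),
        "n_genes_retained": len(rna_kept.feature_ids),
        "n_genes_input": len(dataset.rna_counts.feature_ids),
        "n_degs": sum(r.status != "ns" for r in de),
        "promoter_da_de_pearson_r": r_pearson,
        "promoter_da_de_p": r_p,
        "quadrant_counts": quadrants,
    }

    log.info("stage deviation")
    member = MotifPeakMembership.from_dict(
        dataset.membership, dataset.atac_counts.feature_ids
    )
    gc = np.array([p.gc for p in dataset.peaks])
    scores = compute_deviations(
        dataset.atac_counts, member, gc,
        n_iter=config.n_background,
        seed=config.seed + _SEED_OFFSETS["deviation"],
    )
    variability = variability_rank(scores)
    _write_tsv(
        pd.DataFrame(
            [
                {"motif_id": v.motif_id, "variability": v.variability,
                 "rank": v.rank, "high_variability": v.high_variability}
                for v in variability
            ]
        ),
        out / "motif_variability.tsv",
        config,
    )
    zdf = pd.DataFrame(
        scores.z, index=scores.motif_ids, columns=scores.sample_ids
    ).reset_index(names="motif_id")
    _write_tsv(zdf, out / "motif_deviation_z.tsv", config)
    report["stages"]["deviation"] = {
        "n_motifs": len(scores.motif_ids),
        "n_background": scores.n_background,
        "top_variability_motif": variability[0].motif_id,
        "n_high_variability": sum(v.high_variability for v in variability),
    }

    log.info("stage footprint")
    depth_rows = []
    for motif_id, occs in dataset.occurrences.items():
        for cond in ("A", "B"):
            prof = aggregate_footprint(
                dataset.cut_tracks[cond], occs, flank=config.flank,
                condition=cond,
            )
            d = footprint_depth(prof)
            depth_rows.append(
                {"motif_id": motif_id, "condition": cond, "depth": d.depth,
                 "n_occurrences": prof.n_occurrences}
            )
    depth_df = pd.DataFrame(depth_rows)
    _write_tsv(depth_df, out / "footprint_depth.tsv", config)
    wide = depth_df.pivot(index="motif_id", columns="condition",
                          values="depth")
    bound = config.synthetic.bound_motif
    report["stages"]["footprint"] = {
        "n_motifs": int(wide.shape[0]),
        "bound_motif": bound,
        "bound_motif_delta_depth": float(
            wide.loc[bound, "B"] - wide.loc[bound, "A"]
        ) if bound in wide.index else None,
    }

    log.info("stage superenhancer")
    by_id = {p.id: p for p in peaks}
    calls = {}
    curves = {}
    for cond, ids in (("A", dataset.peaks_a), ("B", dataset.peaks_b)):
        calls[cond], curves[cond] = call_superenhancers(
            [by_id[i] for i in ids],
            dataset.genes,
            dataset.cut_tracks[cond],
            dataset.background,
            condition=cond,
            stitch_gap=config.stitch_gap,
            tss_upstream=config.tss_upstream,
            tss_downstream=config.tss_downstream,
        )
    calls_a, calls_b, venn = categorize_ses(calls["A"], calls["B"])
    rna_cpm = cpm(rna_kept)
    abundance = {
        g: float(np.log2(rna_cpm[i].mean() + 1.0))
        for i, g in enumerate(rna_kept.feature_ids)
    }
    integration = integrate_expression(calls_a + calls_b, de, abundance)
    se_rows = []
    for cond, cc in (("A", calls_a), ("B", calls_b)):
        for c in cc:
            iv = c.region.interval
            se_rows.append(
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "name": f"{cond}_region_{c.rank}", "signal": c.signal,
                 "strand": ".", "condition": cond, "rank": c.rank,
                 "is_se": c.is_se, "category": c.category,
                 "assigned_gene": c.assigned_gene}
            )
    _write_tsv(pd.DataFrame(se_rows), out / "superenhancers.tsv", config)
    _write_tsv(
        pd.DataFrame(
            {"category": ["a_only", "b_only", "shared"],
             "count": [venn.a_only, venn.b_only, venn.shared]}
        ),
        out / "se_venn.tsv",
        config,
    )
    report["stages"]["superenhancer"] = {
        "n_regions_a": len(calls_a),
        "n_regions_b": len(calls_b),
        "n_se_a": sum(c.is_se for c in calls_a),
        "n_se_b": sum(c.is_se for c in calls_b),
        "venn": {"a_only": venn.a_only, "b_only": venn.b_only,
                 "shared": venn.shared, "total_units": venn.total_units},
        "expression_tallies": integration.tallies,
        "abundance_comparison": integration.abundance_comparison,
    }

    log.info("stage enrich")
    universe = set(rna_kept.feature_ids)
    up = {r.feature_id for r in de if r.status == "up"}
    down = {r.feature_id for r in de if r.status == "down"}
    sets_in_universe = {
        s: members & universe for s, members in dataset.gene_sets.items()
        if members & universe
    }
    ora_rows = []
    for direction, hits in (("up", up), ("down", down)):
        if not hits:
            continue
        for r in ora_test(hits, universe, sets_in_universe):
            ora_rows.append(
                {"direction": direction, "set_id": r.set_id,
                 "overlap": r.overlap, "set_size": r.set_size,
                 "hits_size": r.hits_size, "universe": r.universe,
                 "p": r.p, "adj_p": r.adj_p,
                 "fold_enrichment": r.fold_enrichment}
            )
    _write_tsv(pd.DataFrame(ora_rows), out / "ora_results.tsv", config)

    ranked = sorted(
        ((r.feature_id, r.log2fc) for r in de), key=lambda t: -t[1]
    )
    gsea_rows = []
    for i, (set_id, members) in enumerate(sorted(sets_in_universe.items())):
        if not (set(g for g, _ in ranked) & members):
            continue
        res = gsea_preranked(
            ranked, members, n_perm=config.n_perm,
            seed=config.seed + _SEED_OFFSETS["gsea"] + i,
        )
        gsea_rows.append(
            {"set_id": set_id, "es": res.es, "nes": res.nes, "p": res.p,
             "n_perm": res.n_perm}
        )
    _write_tsv(pd.DataFrame(gsea_rows), out / "gsea_results.tsv", config)

    b_only_regions = [
        c.region.interval for c in calls_b if c.is_se and c.category == "b_only"
    ]
    all_regions_b = [c.region.interval for c in calls_b]
    motif_rows = []
    if b_only_regions:
        for r in motif_enrichment_in_regions(
            b_only_regions, all_regions_b, dataset.occurrences
        ):
            motif_rows.append(
                {"motif_id": r.set_id, "overlap": r.overlap,
                 "set_size": r.set_size, "hits_size": r.hits_size,
                 "universe": r.universe, "p": r.p, "adj_p": r.adj_p,
                 "fold_enrichment": r.fold_enrichment}
            )
    _write_tsv(
        pd.DataFrame(
            motif_rows,
            columns=["motif_id", "overlap", "set_size", "hits_size",
                     "universe", "p", "adj_p", "fold_enrichment"],
        ),
        out / "se_motif_enrichment.tsv",
        config,
    )
    report["stages"]["enrich"] = {
        "n_gene_sets": len(sets_in_universe),
        "n_gsea_tested": len(gsea_rows),
        "n_b_only_se_regions": len(b_only_regions),
    }

    report["truth_recovery"] = _truth_recovery(
        truth, da, de, scores, calls_a, calls_b
    )
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_report.txt", "w") as fh:
        fh.write(f"{_header(config)}\n")
        for stage, info in report["stages"].items():
            fh.write(f"[{stage}] {json.dumps(info, sort_keys=True)}\n")
    return report


def _truth_recovery(truth, da, de, scores, calls_a, calls_b) -> dict:
    """Planted-truth recovery metrics for the run report."""
    out: dict = {}
    # differential accessibility
    da_by_id = {r.feature_id: r for r in da}
    strong = {
        pid: fc for pid, fc in truth.planted_da_peaks.items()
        if abs(fc) > 1.0 and pid in da_by_id
    }
    if strong:
        hit = sum(
            1 for pid, fc in strong.items()
            if da_by_id[pid].status == ("up" if fc > 0 else "down")
        )
        out["da_recall"] = hit / len(strong)
    called = [r for r in da if r.status != "ns"]
    if called:
        true_ids = set(truth.planted_da_peaks)
        out["da_precision"] = sum(
            1 for r in called if r.feature_id in true_ids
        ) / len(called)
    # differential expression
    de_by_id = {r.feature_id: r for r in de}
    planted_de = {
        g: fc for g, fc in truth.planted_de_genes.items() if g in de_by_id
    }
    if planted_de:
        hit = sum(
            1 for g, fc in planted_de.items()
            if de_by_id[g].status == ("up" if fc > 0 else "down")
        )
        out["de_recall"] = hit / len(planted_de)
    # motif deviation
    zmap = dict(zip(scores.motif_ids, scores.z))
    b_cols = [i for i, s in enumerate(scores.sample_ids) if s.startswith("B")]
    shifted = {}
    for m, s in truth.planted_motif_shifts.items():
        if m in zmap:
            shifted[m] = float(np.nanmean(zmap[m][b_cols])) * (
                1 if s > 0 else -1
            )
    if shifted:
        out["planted_motif_mean_signed_z"] = shifted
    # super-enhancers
    se_truth = truth.planted_se_regions
    called_ses = [c for c in calls_a + calls_b if c.is_se]
    if se_truth:
        recovered = 0
        for iv, _cat in se_truth:
            if any(c.region.interval.overlaps(iv) for c in called_ses):
                recovered += 1
        out["se_recall"] = recovered / len(se_truth)
    if called_ses:
        out["se_precision"] = sum(
            1 for c in called_ses
            if any(c.region.interval.overlaps(iv) for iv, _ in se_truth)
        ) / len(called_ses)
    return out
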