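# peakscape

Downstream integration of ATAC-seq and RNA-seq for two-condition
experiments — the analysis layer that starts *after* alignment and peak
calling. Given called peaks, count matrices, per-base cut-site tracks,
motif annotations and gene models, it answers the questions a regulatory
genomics study asks of such data:

* **Where are the peaks?** Annotation by genomic region (promoter, 5'/3'
  UTR, exon, intron, distal intergenic) against a TSS window (±1 kb by
  default).
* **What changed?** CPM filtering (CPM > 1 in ≥ 3 samples), TMM
  normalization, and a moderated-t differential test with the standard
  criterion |log2FC| > 1 and BH-adjusted p < 0.05, for both peak
  accessibility and gene expression — plus the promoter-accessibility
  versus transcript-fold-change correlation that links them.
* **Which factors drive it?** Per-motif accessibility deviation scores
  z = (Y − mean Y_bg) / sd(Y_bg), where Y = (X − E)/E compares observed
  motif-peak counts X with the expectation E under the all-sample average
  profile, and backgrounds are GC- and accessibility-matched peak sets;
  motifs are ranked by cross-sample variability (SD of z) with an elbow
  cutoff.
* **Are they bound?** Aggregate TF footprints: per-million-normalized
  cut-site profiles around motif centers, summarized by a depth statistic
  (flank mean − core mean with a 5 bp guard band) and compared between
  conditions.
* **Where are the super-enhancers?** ROSE-style calling: exclude
  TSS-proximal peaks (−1000/+100 bp), stitch peaks closer than 12.5 kb,
  score each stitched region by depth-normalized treatment coverage minus
  input-DNA background, and call regions above the tangent-slope-1
  inflection of the ranked-signal curve. SEs from two conditions are
  categorized shared / A-only / B-only and integrated with expression.
* **What is enriched?** Hypergeometric over-representation (gene sets
  from GMT, or motifs in SE categories) and preranked GSEA with
  permutation p-values and NES.

Every stage is exercised end-to-end on a built-in synthetic-data
generator that plants recoverable ground truth (differential peaks and
genes, motif shifts, protected footprints, SE clusters), so the whole
pipeline is testable without any external data.

## Worked example

```sh
peakscape all --seed 5 --outdir demo_run
```

simulates a 4 × 9 Mb genome with 600 genes, 2,100 consensus peaks
(including 20 planted SE clusters of 5 high-signal peaks), two conditions
× 3 replicates, then runs every stage. It prints the planted-truth
recovery summary:

```json
{
  "da_precision": 0.978448275862069,
  "da_recall": 0.8805970149253731,
  "de_recall": 0.9888888888888889,
  "planted_motif_mean_signed_z": {
    "motif_000": 3.949042108566278,
    "motif_001": 4.878888867879502
  },
  "se_precision": 0.967741935483871,
  "se_recall": 1.0
}
```

Reading this: ~88% of peaks planted with a true |log2FC| > 1 are
recovered as differentially accessible with ~98% precision; planted
differentially expressed genes are recovered at ~99%; the two motifs
planted with ±1 log2 accessibility shifts score mean |z| ≈ 4–5 in the
shifted condition; and all 20 planted super-enhancer clusters are
re-identified with ~97% precision. `demo_run/` holds the per-stage
tables (`peak_annotation.tsv`, `differential_*.tsv`,
`motif_deviation_z.tsv`, `footprint_depth.tsv`, `superenhancers.tsv`,
`se_venn.tsv`, `ora_results.tsv`, `gsea_results.tsv`) and
`run_report.json` with stage counts; every table carries a header
comment with the version, seed, and parameter hash, and reruns with the
same seed are byte-identical.

The same stages are available as subcommands (`simulate`, `annotate`,
`differential`, `deviation`, `footprint`, `se`, `enrich`) and as a
library API (`peakscape.differential_test`, `compute_deviations`,
`call_superenhancers`, `gsea_preranked`, ...).

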