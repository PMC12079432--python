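# Methods

This note documents the models, parameter choices and numerical
conventions behind peakscape, and what the synthetic validation does and
does not demonstrate.

## Coordinates and peak annotation

All coordinates are BED-convention 0-based half-open internally; 1-based
numbers appear only in text formats that require them. Consensus peaks
are the base-pair union of two conditions' peak sets; book-ended
intervals are merged (bedtools-merge semantics) so the output covers
exactly the union.

A peak is *promoter* when any TSS lies within `promoter_window`
(default ±1000 bp) of any peak base. Otherwise, a peak overlapping a
gene is classified by the priority promoter > 5'UTR > 3'UTR > exon >
intron; anything else is distal intergenic. The priority order is a
convention (common annotators behave this way) and is configurable — it
only matters for peaks straddling multiple features. The closest gene
minimizes |peak center − TSS| with lexicographic gene-id tie-breaking,
purely for determinism. Note that the promoter annotation window
(±1000 bp, symmetric) and the super-enhancer TSS exclusion window
(−1000/+100 bp, strand-relative) are deliberately distinct parameters:
they serve different steps and are never conflated.

## Normalization and the differential test

CPM is counts / (library size × scaling factor) × 10⁶. Expression
filtering keeps features with CPM > 1 (raw library sizes) in ≥ 3
samples. TMM scaling factors follow the trimmed-mean-of-M-values
construction: log2 ratios versus a reference column (the sample whose
75th CPM percentile is closest to the mean of those percentiles),
doubly trimmed (30% of M-values, 5% of A-values, each tail), averaged
with inverse-asymptotic-variance weights, then rescaled to geometric
mean 1. A sample whose library is inflated by a handful of extreme
features therefore gets a factor below 1, raising the CPM of its
ordinary features back into line.

The two-group differential test is deliberately *not* a
negative-binomial GLM: the pipeline's downstream logic depends only on
the thresholded criterion (|log2FC| > 1, BH-adjusted p < 0.05), so a
simpler test with honest error control suffices. We use a moderated t
on log2(CPM + 0.5): per-feature pooled variances are shrunk toward a
common prior fitted by the scaled-F moment method (log-variance mean and
spread matched via digamma/trigamma, with a Newton trigamma inverse),
and the t statistic gains the prior degrees of freedom. At n = 3 vs 3 a
plain Welch t cannot push p-values much below ~10⁻³ and loses almost all
power after BH across thousands of features; variance moderation
restores it while the null simulations in the test suite confirm the
BH-adjusted type-I error stays at or below nominal. Fold changes use
prior count 0.5 on TMM-normalized mean CPM. BH ties keep input order.

The promoter integration pairs each promoter-annotated peak's
accessibility log2FC with its closest gene's expression log2FC and
reports Pearson r plus quadrant counts restricted to pairs with both
|log2FC| > 1.

## Motif accessibility deviations

For motif *j* and sample *i*, X is the count in the motif's member
peaks and the expectation is E[j,i] = t_i × mean over samples of
(X[j,s]/t_s) — the average fraction of each sample's reads falling in
those peaks, scaled to the sample's depth. The mean-of-fractions form
(rather than fraction of the grand total) makes the raw deviation
Y = (X − E)/E *exactly* invariant to rescaling any one sample's depth,
which the test suite asserts bit-exactly.

Backgrounds: peaks are binned into a 10 × 10 equal-occupancy grid of GC
fraction × log mean CPM, and each member peak is replaced by a uniform
draw from its own bin, 50 iterations by default (`n_background`). This
is simpler and more directly testable than nearest-neighbour sampling
in a whitened GC/accessibility space; the trade-off is coarser matching
at bin edges. The bias-corrected deviation is Y − mean(Y_bg) and
z = corrected / sd(Y_bg) (sample SD, n−1). Cells with zero background
spread are reported missing unless the correction is also exactly zero
(then z = 0). Motif variability is the cross-sample SD of z; the
high-variability set sits above the elbow of the variability-versus-rank
curve, using the same elbow routine as the super-enhancer threshold so
the package has a single inflection definition.

On null synthetic data (no planted shifts) the z-scores are close to
standard normal (pooled |mean| < 0.1, SD ≈ 0.9–1.0 in the test suite),
so deviation magnitudes can be read roughly as z units.

## Footprints

Aggregate profiles average per-base cut counts over motif occurrences
(minus-strand windows reversed), scaled by 10⁶/total cuts, over the
motif plus a 100 bp flank each side. Occurrences extending past
chromosome ends are skipped, not padded. Depth = flank mean − core mean,
where the core is |offset| ≤ width/2, the flank band is
(width/2 + 5, flank], and the 5 bp guard band between them belongs to
neither — a declared operationalization chosen because it is simple and
monotone in true protection (verified on a planted protection grid).
For an even motif width the |offset| ≤ w/2 core includes one base past
the motif edge; the planted-protection recovery tests therefore measure
the core over the exact occurrence footprint. Tn5 sequence bias is not
modeled anywhere: synthetic tracks carry none, and no bias correction is
applied — footprint conclusions on real data would need bias-aware
preprocessing upstream.

## Super-enhancers

Peaks within the strand-relative window 1 kb upstream to 100 bp
downstream of any TSS are excluded; remaining peaks with inter-peak gaps
strictly less than 12.5 kb are stitched. Each stitched region's signal
is the treatment coverage minus input-DNA background coverage over its
constituent peak intervals, each first scaled to per-million of its own
track total (subtraction across libraries of different depth is
meaningless otherwise), floored at 0.

The threshold: signals sorted ascending, rank and signal rescaled to
[0,1]; the cutoff sits where the tangent slope of the scaled curve
equals 1, found discretely as the point of maximal vertical distance
below the diagonal; regions with signal strictly above the threshold
signal are super-enhancers. This is exactly scale-invariant. A known
property of this criterion: on a heavy-tailed (e.g. exponential) null
the tangent point falls where the scaled slope is 1, which leaves
roughly (n−1)/max-signal null regions above the threshold — the
criterion controls the *shape* of the cut, not a false-positive count.
On realistic planted data (clusters at ~10× background) the separation
is large and recovery is near-perfect.

Cross-condition categories use ≥ 1 bp overlap between called SEs
(book-ended regions do not count); Venn counts merge overlapping
cross-condition SEs into units so that a_only + b_only + shared
partitions the SE universe exactly. SE-to-gene assignment is nearest
TSS to the region midpoint. Expression integration labels each
SE-assigned gene by its differential status and compares abundance
(log2(CPM+1)) of SE-assigned vs regular-enhancer-assigned vs all other
genes with one-sided rank-sum tests.

## Enrichment

ORA is the upper-tail hypergeometric P(X ≥ k) with the universe
defaulting to the post-filter gene set, BH-adjusted across sets; the
region-level variant declares a region motif-positive if ≥ 1 occurrence
overlaps it and uses regions as the universe (a deliberate,
documented simplification of rank-based motif-enrichment tools).
Preranked GSEA uses the weighted running sum (hits weighted by
|score|^w, w = 1 by default; misses by 1/(N−K)); ES is the
maximum-magnitude excursion, evaluated in the permutation loop only at
hit positions (the running sum is linear between hits, so extrema occur
there). Significance comes from random same-size gene-label sets: p is
one-sided among same-signed permuted scores with a +1 correction, and
NES divides ES by the mean |permuted ES| of the same sign. Null
calibration (random sets) gives uniform p by KS test. A single hit at
the top of the list yields ES = 1.0 — the running sum peaks at the hit
before the misses walk it down.

## Synthetic data: what it emulates, and what it does not

The generator lays out distal peaks, genes (with promoter peak centered
on the TSS, exons, UTRs) and SE clusters (5 peaks, gaps ~0.8–2.2 kb)
along a 4 × 9 Mb genome, with ~12.6–15 kb between units so unrelated
peaks never stitch. Defaults: 2,000 regular peaks, 600 genes, 20 SE
clusters (10 shared / 5 A-only / 5 B-only), 50 motifs × 200 member
peaks, two conditions × 3 replicates.

Counts are negative binomial (dispersion 0.1, typical of bulk
replicates) with mean = baseline (lognormal around 100) × condition
effect × library-size factor × a multiplicative GC term
2^(gc − 0.5) — the latter gives the deviation module's GC matching
something real to correct. Planted condition-B effects: ±1 log2 at the
member peaks of designated motifs; ±1.5 log2 at promoter peaks of DE
genes (sign matching the gene's ±2 log2 expression shift with
probability 0.8); ×10 at cluster peaks in their active conditions.
Condition-specific cluster peaks appear only in their own condition's
peak list, as a real peak caller would produce. RNA counts couple DE to
SE categories (B-only SE target genes are upregulated with probability
0.8, A-only downregulated) and SE target genes get a +2 log2 baseline
abundance offset, mirroring the elevated expression of SE-associated
genes. Cut-site tracks are per-base Poisson inside peaks (0.2/bp
regular, 2.0/bp in active clusters) with bound-motif cores thinned by
the protection fraction (0.5) in condition B only; the input-DNA
background is Poisson around a constant 0.1/bp in 200 bp bins. Effect
sizes and rates not fixed by the study design were chosen once as
realistic bulk-ATAC magnitudes and are config fields, not tuned values.

Not emulated: Tn5 sequence bias, fragment-length structure, mitochondrial
and duplicate artifacts, batch effects, overlapping genes, multi-TSS
isoforms, and read-level data. Passing tests therefore demonstrate the
*logic* of each stage on data with the right count statistics, not
robustness to these real-data complications.

Everything is a pure function of one seed (the pipeline fans it out to
per-stage seeds by fixed offsets); two runs with the same seed produce
byte-identical outputs, which the suite asserts file-by-file.

## Problem sizes

Default problem sizes (2,000 peaks, 600 genes, 50 motifs, 50 background
iterations, 1,000 GSEA permutations, 4 × 9 Mb genome) were chosen so a
full pipeline run completes in well under a minute on one CPU while
keeping count statistics in the regime of real experiments; the
multi-seed validation suites rerun the generator ten times at these
sizes.
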