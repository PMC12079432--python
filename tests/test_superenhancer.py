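import numpy as np
import pytest

from peakscape.core import GeneModel, GenomicInterval, Peak
from peakscape.elbow import find_inflection
from peakscape.footprint import CutSiteTrack
from peakscape.norm import DifferentialResult
from peakscape.superenhancer import (
    SuperEnhancerCall,
    StitchedRegion,
    assign_closest_gene,
    categorize_ses,
    exclude_tss_proximal,
    integrate_expression,
    region_signal,
    stitch,
)


def peak(start, end, chrom="chr1", pid=None):
    return Peak(pid or f"p{start}", GenomicInterval(chrom, start, end))


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    return GeneModel(gene_id, gene_id.upper(),
                     GenomicInterval(chrom, start, end, strand))


class TestExcludeTssProximal:
    def test_peak_covering_plus_strand_tss_excluded(self):
        g = gene("g1", 5000, 9000, "+")
        kept = exclude_tss_proximal([peak(4950, 5050)], [g])
        assert kept == []

    def test_peak_past_downstream_window_retained(self):
        g = gene("g1", 5000, 9000, "+")  # window [4000, 5100]
        kept = exclude_tss_proximal([peak(5150, 5160)], [g])
        assert len(kept) == 1

    def test_zero_windows_remove_only_tss_overlap(self):
        g = gene("g1", 5000, 9000, "+")
        kept = exclude_tss_proximal(
            [peak(4999, 5000), peak(5000, 5001)], [g],
            upstream=0, downstream=0,
        )
        assert [p.interval.start for p in kept] == [4999]

    def test_minus_strand_window_is_strand_relative(self):
        g = gene("g1", 5000, 9000, "-")  # TSS 8999, window [8899, 9999]
        assert exclude_tss_proximal([peak(9500, 9600)], [g]) == []
        assert len(exclude_tss_proximal([peak(8000, 8100)], [g])) == 1


def brute_force_stitch(peaks, gap):
    """Union-find transitive-closure merge oracle."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i].interval, peaks[j].interval
            if a.chrom != b.chrom:
                continue
            gap_ij = max(a.start, b.start) - min(a.end, b.end)
            if gap_ij < gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    return {
        (
            g[0].interval.chrom,
            min(p.interval.start for p in g),
            max(p.interval.end for p in g),
        )
        for g in groups.values()
    }


class TestStitch:
    def test_gap_below_threshold_merges(self):
        regions = stitch([peak(0, 100), peak(12599, 12700)])
        assert len(regions) == 1
        assert regions[0].interval == GenomicInterval("chr1", 0, 12700)

    def test_gap_at_threshold_does_not_merge(self):
        regions = stitch([peak(0, 100), peak(12600, 12700)])
        assert len(regions) == 2

    def test_matches_union_find_oracle(self, rng):
        peaks = [
            peak(int(s), int(s) + int(w), chrom=f"chr{c}", pid=f"q{i}")
            for i, (s, w, c) in enumerate(
                zip(
                    rng.integers(0, 2_000_000, 400),
                    rng.integers(100, 800, 400),
                    rng.integers(1, 3, 400),
                )
            )
        ]
        got = {
            (r.interval.chrom, r.interval.start, r.interval.end)
            for r in stitch(peaks)
        }
        assert got == brute_force_stitch(peaks, 12500)

    def test_idempotent_on_own_output(self, rng):
        peaks = [
            peak(int(s), int(s) + 200, pid=f"q{i}")
            for i, s in enumerate(rng.integers(0, 500_000, 100))
        ]
        regions = stitch(peaks)
        again = stitch(
            [peak(r.interval.start, r.interval.end, pid=f"r{i}")
             for i, r in enumerate(regions)]
        )
        assert [r.interval for r in again] == [r.interval for r in regions]


class TestRegionSignal:
    def _region(self, *peak_bounds):
        peaks = [peak(s, e) for s, e in peak_bounds]
        return StitchedRegion(
            GenomicInterval("chr1", peak_bounds[0][0], peak_bounds[-1][1]),
            peaks,
        )

    def test_background_equal_to_treatment_gives_zero(self, rng):
        arr = rng.poisson(2.0, 2000).astype(float)
        t = CutSiteTrack({"chr1": arr})
        b = CutSiteTrack({"chr1": arr.copy()})
        region = self._region((100, 300), (500, 800))
        assert region_signal(region, t, b) == 0.0

    def test_zero_background_gives_normalized_treatment(self):
        arr = np.full(2000, 3.0)
        t = CutSiteTrack({"chr1": arr})
        b = CutSiteTrack({"chr1": np.zeros(2000)})
        region = self._region((100, 200))
        assert region_signal(region, t, b) == pytest.approx(
            300 * 1e6 / arr.sum()
        )

    def test_toy_region_matches_hand_sum(self):
        t_arr = np.zeros(1000)
        t_arr[10:20] = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]  # sum 55
        t_arr[100:103] = [5, 5, 5]  # sum 15
        b_arr = np.full(1000, 0.5)
        region = self._region((10, 20), (100, 103))
        t = CutSiteTrack({"chr1": t_arr})
        b = CutSiteTrack({"chr1": b_arr})
        expected = (55 + 15) * 1e6 / t_arr.sum() - (
            0.5 * 13
        ) * 1e6 / b_arr.sum()
        assert region_signal(region, t, b) == pytest.approx(expected)

    def test_signal_floors_at_zero(self):
        t = CutSiteTrack({"chr1": np.full(1000, 0.1)})
        b = CutSiteTrack({"chr1": np.full(1000, 10.0)})
        region = self._region((0, 100))
        # identical per-million profiles -> exactly 0 after normalization;
        # make background relatively heavier inside the region
        b.arrays["chr1"][:100] *= 50
        b._total = None
        assert region_signal(region, t, b) == 0.0


class TestFindInflection:
    def test_scale_invariance_is_exact(self, rng):
        signals = np.sort(rng.exponential(1.0, 500))[::-1]
        base = find_inflection(signals)
        for c in (7.0, 0.001, 3e6):
            assert find_inflection(signals * c).threshold_index == \
                base.threshold_index

    def test_hockey_stick_keeps_planted_population_above_threshold(
        self, rng
    ):
        # the slope-1 tangent on an exponential null tail sits where the
        # scaled slope is 1, i.e. ~(n-1)/ymax null values stay above it
        null = rng.exponential(1.0, 1900)
        high = rng.exponential(1.0, 100) + 20
        curve = find_inflection(np.concatenate([null, high]))
        thr = curve.threshold_signal
        assert np.sum(high > thr) >= 95
        assert np.sum(null > thr) <= 150

    def test_linear_curve_degenerates_with_warning(self):
        # exactly-representable linear curve: elbow sits at an extreme
        with pytest.warns(UserWarning):
            curve = find_inflection(np.arange(50.0))
        assert curve.threshold_index in (0, 1, 49, 50)

    def test_flat_curve_yields_no_calls(self):
        with pytest.warns(UserWarning, match="flat"):
            curve = find_inflection(np.ones(20))
        assert curve.threshold_index == 0

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            find_inflection(np.arange(5))


class TestAssignClosestGene:
    def test_region_containing_tss_wins(self):
        genes = [gene("g1", 5000, 9000), gene("g2", 50_000, 60_000)]
        region = StitchedRegion(
            GenomicInterval("chr1", 4000, 6000), [peak(4000, 6000)]
        )
        assert assign_closest_gene(region, genes) == "g1"

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = [gene("gb", 0, 1000), gene("ga", 3000, 4000)]
        # midpoints: TSS gb=0, ga=3000; region midpoint 1500
        region = StitchedRegion(
            GenomicInterval("chr1", 1000, 2001), [peak(1000, 2001)]
        )
        assert assign_closest_gene(region, genes) == "ga"

    def test_matches_brute_force_scan(self, rng):
        genes = [
            gene(f"g{i}", int(s), int(s) + 2000)
            for i, s in enumerate(
                np.sort(rng.integers(0, 3_000_000, 60)) * 1
            )
        ]
        for _ in range(100):
            s = int(rng.integers(0, 2_900_000))
            region = StitchedRegion(
                GenomicInterval("chr1", s, s + 500), [peak(s, s + 500)]
            )
            mid = region.interval.center
            best = min(
                genes, key=lambda g: (abs(mid - g.tss), g.gene_id)
            )
            assert assign_closest_gene(region, genes) == best.gene_id


def se_call(start, end, is_se=True, chrom="chr1", gene_id=None, rank=1):
    region = StitchedRegion(
        GenomicInterval(chrom, start, end), [peak(start, end)]
    )
    return SuperEnhancerCall(region, signal=1.0, rank=rank, is_se=is_se,
                             assigned_gene=gene_id)


class TestCategorizeSes:
    def test_identical_lists_all_shared(self):
        a = [se_call(0, 1000), se_call(5000, 6000)]
        b = [se_call(0, 1000), se_call(5000, 6000)]
        ca, cb, venn = categorize_ses(a, b)
        assert all(c.category == "shared" for c in ca + cb)
        assert (venn.a_only, venn.b_only, venn.shared) == (0, 0, 2)

    def test_disjoint_lists_have_no_shared(self):
        a = [se_call(0, 1000)]
        b = [se_call(5000, 6000)]
        _, _, venn = categorize_ses(a, b)
        assert venn.shared == 0
        assert venn.a_only == 1 and venn.b_only == 1

    def test_counts_partition_merged_units(self, rng):
        a = [se_call(int(s), int(s) + 500, is_se=True)
             for s in rng.integers(0, 200_000, 30)]
        b = [se_call(int(s), int(s) + 500, is_se=True)
             for s in rng.integers(0, 200_000, 30)]
        _, _, venn = categorize_ses(a, b)
        # merged cross-condition units under the >=1 bp overlap rule
        from tests_support import overlap_unit_count
        ivs = [c.region.interval for c in a + b]
        assert venn.total_units == overlap_unit_count(ivs)

    def test_non_se_calls_ignored(self):
        a = [se_call(0, 1000, is_se=False)]
        b = [se_call(0, 1000)]
        _, _, venn = categorize_ses(a, b)
        assert (venn.a_only, venn.b_only, venn.shared) == (0, 1, 0)


class TestIntegrateExpression:
    def _de(self, gene_id, status, fc=0.0):
        return DifferentialResult(gene_id, fc, 0.01, 0.01, status)

    def test_empty_de_list_excludes_everything(self):
        calls = [se_call(0, 1000, gene_id="g1")]
        calls[0].category = "shared"
        out = integrate_expression(calls, [], {"g1": 5.0})
        assert out.records == [] and out.tallies == {}
        assert out.missing_genes == ["g1"]

    def test_tallies_follow_de_status(self):
        calls = []
        for i, (cat, status) in enumerate(
            [("b_only", "up"), ("b_only", "up"), ("b_only", "down"),
             ("shared", "ns")]
        ):
            c = se_call(i * 10_000, i * 10_000 + 500, gene_id=f"g{i}")
            c.category = cat
            calls.append(c)
        de = [self._de(f"g{i}", s)
              for i, s in enumerate(["up", "up", "down", "ns"])]
        out = integrate_expression(calls, de, {f"g{i}": 1.0
                                               for i in range(4)})
        assert out.tallies["b_only"] == {"up": 2, "down": 1, "unchanged": 0}
        assert out.tallies["shared"] == {"up": 0, "down": 0, "unchanged": 1}

    def test_planted_abundance_offset_detected_by_rank_sum(self, rng):
        abundance = {f"o{i}": float(v)
                     for i, v in enumerate(rng.normal(5, 1, 400))}
        calls = []
        for i in range(25):
            g = f"se{i}"
            abundance[g] = float(rng.normal(7, 1))  # +2 log2 offset
            c = se_call(i * 50_000, i * 50_000 + 500, gene_id=g)
            c.category = "shared"
            calls.append(c)
        de = [self._de(g, "ns") for g in abundance]
        out = integrate_expression(calls, de, abundance)
        assert out.abundance_comparison["p_se_vs_other"] < 0.01
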