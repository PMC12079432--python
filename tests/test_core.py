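import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakscape.core import (
    AnnotationCategory,
    GeneModel,
    GenomicInterval,
    Peak,
    annotate_peak,
    consensus_union,
    gc_content,
    gc_content_interval,
    merge_intervals,
)
from peakscape.io import read_intervals, write_bed, write_narrowpeak


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "start,end,strand",
        [(-1, 10, "."), (10, 10, "."), (10, 5, "."), (0, 10, "x")],
    )
    def test_invalid_rejected(self, start, end, strand):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end, strand)

    def test_overlap_is_half_open(self):
        assert not iv(0, 10).overlaps(iv(10, 20))
        assert iv(0, 11).overlaps(iv(10, 20))
        assert not iv(0, 11).overlaps(iv(10, 20, chrom="chr2"))


class TestReadIntervals:
    def test_bed3_parse_preserves_coordinates(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (rec,) = read_intervals(p, "bed")
        assert rec.interval == iv(100, 200)

    def test_narrowpeak_summit(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t0\t300\tpk1\t17\t+\t5.0\t-1\t-1\t50\n")
        (rec,) = read_intervals(p, "narrowPeak")
        assert rec.summit_offset == 50
        assert rec.score == 17

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_intervals(p, "bed") == []

    @pytest.mark.parametrize(
        "line", ["chr1\t200\t100", "chr1\tx\t100", "chr1\t100\t100"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_intervals(p, "bed")

    def test_bedgraph_returns_values(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t10\t2.5\n")
        (rec,) = read_intervals(p, "bedgraph")
        assert rec.interval == iv(0, 10)
        assert rec.value == 2.5

    def test_bed_round_trip_identity(self, tmp_path):
        peaks = [
            Peak("p1", iv(5, 105, strand="+"), score=3.0),
            Peak("p2", iv(500, 700, chrom="chr2", strand="-"), score=1.5),
        ]
        path = tmp_path / "rt.bed"
        write_bed(peaks, path)
        back = read_intervals(path, "bed")
        assert [(p.id, p.interval, p.score) for p in back] == [
            (p.id, p.interval, p.score) for p in peaks
        ]

    def test_narrowpeak_round_trip_identity(self, tmp_path):
        peaks = [Peak("p1", iv(5, 105), summit_offset=42, score=9.0)]
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(peaks, path)
        (back,) = read_intervals(path, "narrowPeak")
        assert back.interval == peaks[0].interval
        assert back.summit_offset == 42


def brute_force_union(lists):
    """Per-base boolean occupancy oracle for interval merging."""
    cover = {}
    for ivs in lists:
        for x in ivs:
            arr = cover.setdefault(x.chrom, np.zeros(10_000, dtype=bool))
            arr[x.start : x.end] = True
    out = set()
    for chrom, arr in cover.items():
        padded = np.concatenate(([False], arr, [False]))
        d = np.diff(padded.astype(int))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            out.add((chrom, int(s), int(e)))
    return out


class TestConsensusUnion:
    def test_overlap_merges(self):
        out = consensus_union([iv(100, 200)], [iv(150, 250)])
        assert out == [iv(100, 250)]

    def test_disjoint_kept(self):
        out = consensus_union([iv(0, 10)], [iv(20, 30)])
        assert out == [iv(0, 10), iv(20, 30)]

    def test_matches_per_base_oracle_on_random_intervals(self, rng):
        a = [
            iv(int(s), int(s) + int(w), chrom=f"chr{c}")
            for s, w, c in zip(
                rng.integers(0, 9000, 500),
                rng.integers(1, 500, 500),
                rng.integers(1, 4, 500),
            )
        ]
        b = [
            iv(int(s), int(s) + int(w), chrom=f"chr{c}")
            for s, w, c in zip(
                rng.integers(0, 9000, 500),
                rng.integers(1, 500, 500),
                rng.integers(1, 4, 500),
            )
        ]
        got = {
            (x.chrom, x.start, x.end) for x in consensus_union(a, b)
        }
        assert got == brute_force_union([a, b])

    def test_idempotent_and_commutative(self, rng):
        a = [iv(int(s), int(s) + 50) for s in rng.integers(0, 5000, 100)]
        b = [iv(int(s), int(s) + 80) for s in rng.integers(0, 5000, 100)]
        ab = consensus_union(a, b)
        assert consensus_union(ab, []) == ab
        assert consensus_union(b, a) == ab

    def test_mixed_chrom_styles_warn(self):
        with pytest.warns(UserWarning, match="naming"):
            consensus_union([iv(0, 10)], [iv(0, 10, chrom="1")])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)),
        min_size=1,
        max_size=30,
    )
)
def test_merge_intervals_covers_exactly_the_union(pairs):
    ivs = [iv(s, s + w) for s, w in pairs]
    merged = merge_intervals(ivs)
    assert {(x.chrom, x.start, x.end) for x in merged} == brute_force_union(
        [ivs]
    )
    # merged output is disjoint and sorted
    for x, y in zip(merged, merged[1:]):
        assert x.end < y.start or x.chrom != y.chrom


def make_gene(gene_id="gene_a", start=5000, end=15000, strand="+",
              chrom="chr1"):
    exons = [
        GenomicInterval(chrom, start, start + 500, strand),
        GenomicInterval(chrom, end - 500, end, strand),
    ]
    utr5 = [GenomicInterval(chrom, start, start + 100, strand)]
    return GeneModel(gene_id, gene_id.upper(),
                     GenomicInterval(chrom, start, end, strand),
                     exons=exons, utr5=utr5)


class TestAnnotatePeak:
    def test_peak_near_tss_is_promoter(self):
        gene = make_gene()  # TSS at 5000, + strand
        cat, closest, dist = annotate_peak(
            Peak("p", iv(4500, 4800)), [gene]
        )
        assert cat is AnnotationCategory.PROMOTER
        assert closest == "gene_a"
        assert dist == 4650 - 5000  # center upstream of TSS -> negative

    def test_peak_inside_intron_far_from_tss(self):
        gene = make_gene()
        cat, _, _ = annotate_peak(Peak("p", iv(8000, 8300)), [gene])
        assert cat is AnnotationCategory.INTRON

    def test_far_peak_is_distal_intergenic(self):
        gene = make_gene()
        cat, closest, _ = annotate_peak(Peak("p", iv(60000, 60500)), [gene])
        assert cat is AnnotationCategory.DISTAL_INTERGENIC
        assert closest == "gene_a"

    def test_utr5_outranks_exon(self):
        gene = make_gene()
        # overlaps both utr5 and exon1; too far from TSS with window 0
        cat, _, _ = annotate_peak(
            Peak("p", iv(5050, 5200)), [gene], promoter_window=0
        )
        assert cat is AnnotationCategory.UTR5

    def test_zero_window_removes_promoter_category(self):
        gene = make_gene()
        cat, _, _ = annotate_peak(
            Peak("p", iv(4500, 4800)), [gene], promoter_window=0
        )
        assert cat is AnnotationCategory.DISTAL_INTERGENIC

    def test_minus_strand_tss_and_sign(self):
        gene = make_gene(strand="-", start=5000, end=15000)  # TSS 14999
        cat, _, dist = annotate_peak(Peak("p", iv(15500, 15600)), [gene])
        assert cat is AnnotationCategory.PROMOTER
        # center 15550 is past the - strand TSS -> upstream -> negative
        assert dist == 14999 - 15550

    def test_no_genes_on_chrom_gives_distal(self):
        gene = make_gene(chrom="chr9")
        cat, closest, dist = annotate_peak(Peak("p", iv(0, 100)), [gene])
        assert cat is AnnotationCategory.DISTAL_INTERGENIC
        assert closest is None and dist is None


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5)]
    )
    def test_known_sequences(self, seq, expected):
        assert gc_content(seq) == expected

    def test_interval_outside_sequence_errors(self):
        with pytest.raises(ValueError):
            gc_content_interval(iv(0, 100), {"chr1": "ACGT"})

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError):
            gc_content("NNN")
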