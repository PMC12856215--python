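import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import base_set, brute_overlaps, covered_bases
from conftest import random_intervals
from spliceclip.intervals import (
    GeneModel,
    GenomicInterval,
    IntervalError,
    build_feature_space,
    expand,
    merge,
    merge_scored,
    overlaps_any,
    promoter_targets,
    subtract,
)

CHROM_LEN = 10_000
SIZES = {"chr1": CHROM_LEN}


class TestGenomicInterval:
    def test_invalid_start_end(self):
        with pytest.raises(IntervalError, match="start < end"):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(IntervalError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(IntervalError):
            GenomicInterval("chr1", -1, 100)

    def test_error_names_record(self):
        with pytest.raises(IntervalError, match="badsite"):
            GenomicInterval("chr1", 50, 50, name="badsite")

    def test_length(self):
        assert GenomicInterval("chr1", 10, 25).length == 15

    def test_invalid_strand(self):
        with pytest.raises(IntervalError):
            GenomicInterval("chr1", 1, 2, strand="?")


class TestMerge:
    def test_empty(self):
        assert merge([]) == []

    def test_simple_overlap(self):
        got = merge(
            [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 150, 250, "+")],
            strand_aware=True,
        )
        assert got == [GenomicInterval("chr1", 100, 250, "+")]

    def test_book_ended_merge(self):
        got = merge([GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300)])
        assert got == [GenomicInterval("chr1", 100, 300)]

    def test_strand_separation(self):
        got = merge(
            [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 150, 250, "-")],
            strand_aware=True,
        )
        assert len(got) == 2

    def test_strand_aware_requires_strands(self):
        with pytest.raises(IntervalError, match="concrete strand"):
            merge([GenomicInterval("chr1", 1, 5, ".")], strand_aware=True)

    @pytest.mark.parametrize("trial", range(20))
    def test_oracle_covered_bases(self, trial):
        rng = np.random.default_rng(trial)
        ivs = random_intervals(rng, 50, chrom_len=CHROM_LEN)
        for strand_aware in (False, True):
            merged = merge(ivs, strand_aware=strand_aware)
            strands = ("+", "-") if strand_aware else (None,)
            for strand in strands:
                want = base_set(ivs, CHROM_LEN, "chr1", strand)
                got = base_set(merged, CHROM_LEN, "chr1", strand)
                assert np.array_equal(want, got)
            # pairwise-disjoint and sorted
            for a, b in zip(merged, merged[1:]):
                if (a.chrom, a.strand) == (b.chrom, b.strand):
                    assert a.end < b.start

    @given(
        st.lists(
            st.tuples(st.integers(0, 1000), st.integers(1, 100)).map(
                lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, ivs):
        once = merge(ivs)
        assert merge(once) == once

    @given(
        st.lists(
            st.tuples(st.integers(0, 2000), st.integers(1, 200)).map(
                lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
            ),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_covered_base_conservation(self, ivs):
        merged = merge(ivs)
        assert sum(iv.length for iv in merged) == covered_bases(ivs, 2500, "chr1")


class TestMergeScored:
    def test_sums_scores(self):
        got = merge_scored(
            [
                GenomicInterval("chr1", 100, 150, score=4),
                GenomicInterval("chr1", 140, 200, score=6),
            ]
        )
        assert got == [GenomicInterval("chr1", 100, 200, score=10)]

    def test_missing_score_errors(self):
        with pytest.raises(IntervalError, match="score"):
            merge_scored([GenomicInterval("chr1", 1, 5)])


class TestOverlapsAny:
    def test_book_ended_no_overlap(self):
        q = GenomicInterval("chr1", 100, 200, "+")
        assert not overlaps_any(q, [GenomicInterval("chr1", 200, 300, "+")], strand_aware=True)

    def test_one_bp_overlap(self):
        q = GenomicInterval("chr1", 100, 200, "+")
        assert overlaps_any(q, [GenomicInterval("chr1", 199, 300, "+")], strand_aware=True)

    def test_empty_subjects(self):
        assert not overlaps_any(GenomicInterval("chr1", 1, 2), [])

    def test_strand_mismatch(self):
        q = GenomicInterval("chr1", 100, 200, "+")
        s = [GenomicInterval("chr1", 150, 250, "-")]
        assert not overlaps_any(q, s, strand_aware=True)
        assert overlaps_any(q, s, strand_aware=False)

    def test_unstranded_matches_either(self):
        q = GenomicInterval("chr1", 100, 200, ".")
        assert overlaps_any(q, [GenomicInterval("chr1", 150, 250, "-")], strand_aware=True)

    def test_oracle_random_pairs(self):
        rng = np.random.default_rng(99)
        subjects = merge(random_intervals(rng, 60, chrom_len=CHROM_LEN, stranded=False))
        for _ in range(1000):
            q = random_intervals(rng, 1, chrom_len=CHROM_LEN)[0]
            for strand_aware in (False, True):
                assert overlaps_any(q, subjects, strand_aware) == brute_overlaps(
                    q, subjects, strand_aware
                )


class TestExpand:
    def test_interior(self):
        got = expand(GenomicInterval("chr1", 500, 600), SIZES, 200)
        assert (got.start, got.end) == (300, 800)

    def test_left_clip(self):
        got = expand(GenomicInterval("chr1", 50, 100), SIZES, 200)
        assert (got.start, got.end) == (0, 300)

    def test_right_clip(self):
        got = expand(GenomicInterval("chr1", 9900, 9950), SIZES, 200)
        assert (got.start, got.end) == (9700, 10_000)

    def test_flank_zero_identity(self):
        iv = GenomicInterval("chr1", 500, 600, "-")
        assert expand(iv, SIZES, 0) == iv

    def test_strand_preserved(self):
        assert expand(GenomicInterval("chr1", 500, 600, "-"), SIZES, 10).strand == "-"

    def test_unknown_chromosome(self):
        with pytest.raises(IntervalError, match="chrMissing"):
            expand(GenomicInterval("chrMissing", 1, 2), SIZES, 10)


class TestSubtract:
    def test_basic(self):
        got = subtract(
            [GenomicInterval("chr1", 100, 300)], [GenomicInterval("chr1", 150, 200)]
        )
        assert [(iv.start, iv.end) for iv in got] == [(100, 150), (200, 300)]

    def test_oracle(self):
        rng = np.random.default_rng(3)
        a = merge(random_intervals(rng, 30, chrom_len=CHROM_LEN, stranded=False))
        b = merge(random_intervals(rng, 30, chrom_len=CHROM_LEN, stranded=False))
        got = subtract(a, b)
        want = base_set(a, CHROM_LEN, "chr1") & ~base_set(b, CHROM_LEN, "chr1")
        assert np.array_equal(base_set(got, CHROM_LEN, "chr1"), want)


class TestGeneModel:
    def test_tss_plus(self, two_exon_gene):
        assert two_exon_gene.tss == 100

    def test_tss_minus(self):
        exons = (GenomicInterval("chr1", 100, 200, "-"), GenomicInterval("chr1", 300, 400, "-"))
        assert GeneModel("g", "chr1", "-", exons).tss == 399

    def test_no_exons(self):
        with pytest.raises(IntervalError, match="exon"):
            GeneModel("g", "chr1", "+", ())

    def test_unsorted_exons(self):
        exons = (GenomicInterval("chr1", 300, 400, "+"), GenomicInterval("chr1", 100, 200, "+"))
        with pytest.raises(IntervalError):
            GeneModel("g", "chr1", "+", exons)


class TestFeatureSpace:
    def test_single_gap(self, two_exon_gene):
        space = build_feature_space([two_exon_gene])
        introns = space.intronic[("chr1", "+")]
        assert [(iv.start, iv.end) for iv in introns] == [(200, 300)]

    def test_no_genes(self):
        space = build_feature_space([])
        assert space.exonic == {} and space.intronic == {}

    def test_exon_precedence_on_overlap(self):
        g1 = GeneModel(
            "g1", "chr1", "+",
            (GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 900, 1000, "+")),
        )
        # g2's exon sits inside g1's intron
        g2 = GeneModel("g2", "chr1", "+", (GenomicInterval("chr1", 400, 500, "+"),))
        space = build_feature_space([g1, g2])
        want_ex = base_set(
            [GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 400, 500, "+"),
             GenomicInterval("chr1", 900, 1000, "+")], 2000, "chr1", "+")
        got_ex = base_set(space.exonic[("chr1", "+")], 2000, "chr1", "+")
        assert np.array_equal(want_ex, got_ex)
        got_in = base_set(space.intronic[("chr1", "+")], 2000, "chr1", "+")
        # intron bases are the gap minus the embedded exon
        assert not (got_in & got_ex).any()
        assert got_in[200:400].all() and got_in[500:900].all()
        assert not got_in[400:500].any()

    def test_disjoint_on_random_genome(self, toy_genome):
        _, sizes, genes, space = toy_genome
        for key in set(space.exonic) | set(space.intronic):
            chrom, strand = key
            ex = base_set(space.exonic.get(key, ()), sizes[chrom], chrom, strand)
            inn = base_set(space.intronic.get(key, ()), sizes[chrom], chrom, strand)
            assert not (ex & inn).any()

    def test_oracle_labels_on_random_genome(self, toy_genome):
        _, sizes, genes, space = toy_genome
        chrom = genes[0].chrom
        for strand in ("+", "-"):
            sub = [g for g in genes if g.strand == strand]
            ex_want = base_set([e for g in sub for e in g.exons], sizes[chrom], chrom, strand)
            in_raw = base_set(
                [iv for g in sub for iv in g.introns()], sizes[chrom], chrom, strand
            )
            in_want = in_raw & ~ex_want
            assert np.array_equal(
                base_set(space.exonic.get((chrom, strand), ()), sizes[chrom], chrom, strand),
                ex_want,
            )
            assert np.array_equal(
                base_set(space.intronic.get((chrom, strand), ()), sizes[chrom], chrom, strand),
                in_want,
            )


class TestPromoterTargets:
    def test_peak_at_tss(self, two_exon_gene):
        peaks = [GenomicInterval("chr1", 100, 101)]
        assert promoter_targets(peaks, [two_exon_gene]) == {"geneA"}

    def test_boundary_501_excluded(self, two_exon_gene):
        # window is [tss-500, tss+500); a peak ending 501 bp upstream misses it
        peaks = [GenomicInterval("chr1", 0, 100 - 501)] if 100 - 501 > 0 else []
        gene = GeneModel(
            "g", "chr1", "+",
            (GenomicInterval("chr1", 1000, 1100, "+"), GenomicInterval("chr1", 1200, 1300, "+")),
        )
        peaks = [GenomicInterval("chr1", 450, 500)]  # ends at 500 = tss-500 boundary
        assert promoter_targets(peaks, [gene], half_width=500) == set()
        peaks = [GenomicInterval("chr1", 450, 501)]  # reaches into the window
        assert promoter_targets(peaks, [gene], half_width=500) == {"g"}

    def test_strand_agnostic(self):
        gene = GeneModel(
            "g", "chr1", "-",
            (GenomicInterval("chr1", 1000, 1100, "-"), GenomicInterval("chr1", 1200, 1300, "-")),
        )
        peaks = [GenomicInterval("chr1", 1290, 1310, "+")]  # tss = 1299
        assert promoter_targets(peaks, [gene]) == {"g"}

    def test_oracle_random(self, toy_genome):
        _, sizes, genes, _ = toy_genome
        rng = np.random.default_rng(4)
        peaks = random_intervals(rng, 80, chrom_len=sizes[genes[0].chrom], stranded=False)
        got = promoter_targets(peaks, genes, half_width=500)
        want = set()
        for g in genes:
            lo, hi = max(0, g.tss - 500), g.tss + 500
            for p in peaks:
                if p.chrom == g.chrom and max(p.start, lo) < min(p.end, hi):
                    want.add(g.gene_id)
                    break
        assert got == want
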