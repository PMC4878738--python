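"""Interval model, BED I/O and primitive operations against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chrombound.core_intervals import (
    BedParseError,
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    interval_distance,
    merge_within,
    overlaps,
    point_distance,
    read_bed,
    subtract_gaps,
    within_distance,
)

from conftest import random_interval_rows, rows_to_set
from oracles import brute_merge, brute_overlap_mask, brute_within_distance


class TestGenomicInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_length_is_half_open(self):
        assert GenomicInterval("chr1", 100, 200).length == 100


class TestReadBed:
    def test_bed3_line_maps_directly(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        iset = read_bed(p, "bed3")
        assert list(iset) == [GenomicInterval("chr1", 100, 200)]

    def test_narrowpeak_summit_sentinel(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(
            "chr1\t100\t400\tpeak1\t0\t.\t8.5\t6.2\t4.0\t-1\n"
            "chr1\t500\t900\tpeak2\t0\t.\t9.1\t7.0\t5.0\t50\n"
        )
        peaks = list(read_bed(p, "narrowPeak").peaks())
        assert peaks[0].summit is None
        assert peaks[1].summit == 550  # start + offset
        assert peaks[1].fold_enrichment == 9.1
        assert peaks[1].neg_log10_p == 7.0

    def test_unsorted_input_is_sorted(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t5\t10\nchr1\t50\t60\nchr1\t5\t10\n")
        iset = read_bed(p, "bed3")
        rows = [(iv.chrom, iv.start, iv.end) for iv in iset]
        assert rows == sorted(rows)

    def test_sicer_window_fold_column(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("chr1\t0\t200\t55\t3\t1e-8\t4.2\t0.01\n")
        iset = read_bed(p, "sicer_window", sicer_fold_col=6)
        assert iset.df["fold_enrichment"].iloc[0] == 4.2

    @pytest.mark.parametrize(
        "content",
        ["chr1\t100\n", "chr1\t200\t100\n", "chr1\tx\t200\n"],
        ids=["short", "inverted", "nonnumeric"],
    )
    def test_malformed_line_names_line_number(self, tmp_path, content):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + content)
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p, "bed3")


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,min_bp,expected",
        [
            (("chr1", 0, 10), ("chr1", 9, 20), 1, True),
            (("chr1", 0, 10), ("chr1", 10, 20), 1, False),  # half-open adjacency
            (("chr1", 0, 10), ("chr2", 0, 10), 1, False),
            (("chr1", 0, 10), ("chr1", 5, 20), 5, True),
            (("chr1", 0, 10), ("chr1", 6, 20), 5, False),
        ],
    )
    def test_examples(self, a, b, min_bp, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b), min_bp) is expected

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            a_rows = random_interval_rows(rng, 200)
            b_rows = random_interval_rows(rng, 200)
            min_bp = int(rng.integers(1, 500))
            got = rows_to_set(a_rows).overlap_mask(rows_to_set(b_rows), min_bp)
            a_sorted = sorted(a_rows)
            assert got.tolist() == brute_overlap_mask(a_sorted, b_rows, min_bp)

    @given(
        s1=st.integers(0, 1000), l1=st.integers(1, 100),
        s2=st.integers(0, 1000), l2=st.integers(1, 100),
        min_bp=st.integers(1, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetry(self, s1, l1, s2, l2, min_bp):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        assert overlaps(a, b, min_bp) == overlaps(b, a, min_bp)


class TestMergeWithin:
    def test_gap_within_threshold_merges(self):
        s = rows_to_set([("chr1", 0, 1000), ("chr1", 2500, 3000)])
        merged = merge_within(s, 2000)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 3000)]

    def test_gap_beyond_threshold_untouched(self):
        s = rows_to_set([("chr1", 0, 1000), ("chr1", 3500, 4000)])
        merged = merge_within(s, 2000)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 1000), (3500, 4000)]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            rows = random_interval_rows(rng, 500, size=50_000)
            max_gap = int(rng.integers(0, 3000))
            got = [(iv.chrom, iv.start, iv.end) for iv in merge_within(rows_to_set(rows), max_gap)]
            assert got == brute_merge(rows, max_gap)

    def test_idempotent_and_order_independent(self, rng):
        rows = random_interval_rows(rng, 100)
        once = merge_within(rows_to_set(rows), 500)
        twice = merge_within(once, 500)
        assert once.df[["chrom", "start", "end"]].equals(twice.df[["chrom", "start", "end"]])
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        again = merge_within(rows_to_set(shuffled), 500)
        assert once.df[["chrom", "start", "end"]].equals(again.df[["chrom", "start", "end"]])

    def test_covered_length_never_decreases(self, rng):
        rows = random_interval_rows(rng, 50, chroms=("chr1",), size=10_000, max_len=500)
        bitmap = np.zeros(10_000, bool)
        for _, s, e in rows:
            bitmap[s:e] = True
        merged = merge_within(rows_to_set(rows), 0)
        # with max_gap=0, merged length equals union length exactly
        assert merged.total_length == int(bitmap.sum())


class TestWithinDistance:
    def test_boundary_within_1kb(self):
        q = rows_to_set([("chr1", 5000, 5200)])
        hits, anchor_hits = within_distance(q, [("chr1", 6000)], 1000)
        assert hits.tolist() == [True] and anchor_hits.tolist() == [True]

    def test_tss_beyond_1kb(self):
        q = rows_to_set([("chr1", 5000, 5200)])
        hits, _ = within_distance(q, [("chr1", 6500)], 1000)
        assert hits.tolist() == [False]

    def test_overlap_is_distance_zero(self):
        assert point_distance(GenomicInterval("chr1", 4800, 5100), "chr1", 5000) == 0
        assert interval_distance(
            GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20)
        ) == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            q_rows = random_interval_rows(rng, 100)
            a_rows = random_interval_rows(rng, 50)
            points = [(r[0], r[1]) for r in random_interval_rows(rng, 50)]
            d = int(rng.integers(0, 3000))
            q = rows_to_set(q_rows)
            q_sorted = sorted(q_rows)
            for anchors in (a_rows, points):
                anchor_objs = (
                    [GenomicInterval(*r) for r in anchors] if len(anchors[0]) == 3 else anchors
                )
                got_q, got_a = within_distance(q, anchor_objs, d)
                exp_q, exp_a = brute_within_distance(q_sorted, anchors, d)
                assert got_q.tolist() == exp_q
                assert got_a.tolist() == exp_a

    def test_monotone_in_d(self, rng):
        q = rows_to_set(random_interval_rows(rng, 100))
        anchors = [(r[0], r[1]) for r in random_interval_rows(rng, 30)]
        prev = None
        for d in (0, 100, 1000, 10_000):
            hits, _ = within_distance(q, anchors, d)
            if prev is not None:
                assert (hits | prev).tolist() == hits.tolist()  # superset
            prev = hits


class TestSubtractGaps:
    def test_single_gap_complement(self):
        asm = GenomeAssembly({"chr1": 1000}, gaps=[GenomicInterval("chr1", 200, 300)])
        segs = subtract_gaps(asm)["chr1"]
        assert [(s.start, s.end) for s in segs] == [(0, 200), (300, 1000)]
        assert sum(s.length for s in segs) == 900

    def test_no_gaps_identity(self):
        asm = GenomeAssembly({"chr1": 1000})
        assert [(s.start, s.end) for s in subtract_gaps(asm)["chr1"]] == [(0, 1000)]

    def test_length_conservation_random_gaps(self, rng):
        for _ in range(10):
            size = 100_000
            gap_rows = sorted(random_interval_rows(rng, 20, chroms=("chr1",), size=size, max_len=500))
            asm = GenomeAssembly({"chr1": size}, gaps=[GenomicInterval(*g) for g in gap_rows])
            segs = subtract_gaps(asm)["chr1"]
            gap_total = sum(g.length for g in asm.gaps)  # normalized, non-overlapping
            assert sum(s.length for s in segs) == size - gap_total
            # disjoint and sorted
            for s1, s2 in zip(segs, segs[1:]):
                assert s1.end < s2.start or s1.end <= s2.start

    def test_out_of_bounds_gap_rejected(self):
        with pytest.raises(ValueError):
            GenomeAssembly({"chr1": 1000}, gaps=[GenomicInterval("chr1", 900, 1100)])
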