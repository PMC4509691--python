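"""Overlap detection, TSS-window gene assignment and redundancy summaries."""
import random

import numpy as np
import pytest

from conftest import make_indel, make_matrix, make_peak
from tfbs_indel_scan import (
    GeneModel, GenomicInterval, OverlapSummary, assign_genes, find_tfbs_id,
    summarize,
)
from tfbs_indel_scan.tfbs_overlap import (
    WINDOW_FLANKING, WINDOW_UPSTREAM, in_window, signed_tss_distance,
)


def _find(peaks, indels, **kw):
    return find_tfbs_id(peaks, make_matrix(indels, n_samples=2), **kw)


class TestFindTfbsId:
    @pytest.mark.parametrize("first_base,kind,matches", [
        (99, "DEL", False),   # one base left of the peak
        (100, "INS", True),   # boundary inclusion at peak start
        (119, "DEL", True),   # last base of the half-open interval
        (120, "DEL", False),  # peak end is exclusive
    ])
    def test_start_inside_rule(self, first_base, kind, matches):
        records = _find([make_peak(start=100, end=120)],
                        [make_indel(first_base=first_base, kind=kind)])
        assert bool(records) == matches

    def test_long_indels_excluded(self):
        peaks = [make_peak(start=100, end=120)]
        ok = make_indel(first_base=105, length=199, vid="short")
        too_long = make_indel(first_base=110, length=200, vid="long")
        records = _find(peaks, [ok, too_long])
        assert [r.indel.key for r in records] == ["short"]

    def test_chromosome_mismatch_allowed(self):
        records = _find([make_peak(chrom="chr2")], [make_indel(chrom="chr1", first_base=105)])
        assert records == []

    def test_aggregates_all_matching_peaks(self):
        peaks = [make_peak(start=90, end=120, tf="A"),
                 make_peak(start=100, end=130, tf="B"),
                 make_peak(start=200, end=220, tf="C")]
        (rec,) = _find(peaks, [make_indel(first_base=105)])
        assert sorted(p.tf_name for p in rec.affected_peaks) == ["A", "B"]

    def test_matches_brute_force_oracle(self):
        rng = random.Random(11)
        peaks = [make_peak(chrom=f"chr{rng.randint(1, 3)}",
                           start=(s := rng.randrange(0, 5000)),
                           end=s + rng.randint(1, 80),
                           tf=f"TF{rng.randint(0, 5)}") for _ in range(300)]
        peaks = sorted(set(peaks))
        indels = [make_indel(chrom=f"chr{rng.randint(1, 3)}",
                             first_base=rng.randrange(1, 5100),
                             length=rng.randint(1, 10), vid=f"v{i}")
                  for i in range(300)]
        records = _find(peaks, indels)
        got = {(r.indel.key, p.interval.start, p.tf_name)
               for r in records for p in r.affected_peaks}
        expected = {(v.key, p.interval.start, p.tf_name)
                    for v in indels for p in peaks
                    if p.interval.chrom == v.chrom
                    and p.interval.contains(v.first_affected_base())}
        assert got == expected

    def test_raising_max_len_only_adds_records(self):
        rng = random.Random(5)
        peaks = [make_peak(start=s, end=s + 50) for s in range(0, 2000, 60)]
        indels = [make_indel(first_base=rng.randrange(1, 2100),
                             length=rng.randint(1, 150), vid=f"v{i}")
                  for i in range(80)]
        keys = {}
        for max_len in (10, 50, 200):
            keys[max_len] = {r.indel.key for r in _find(peaks, indels, max_len=max_len)}
        assert keys[10] <= keys[50] <= keys[200]

    def test_input_order_irrelevant(self):
        rng = random.Random(7)
        peaks = [make_peak(start=s, end=s + 30, tf=f"TF{s % 4}") for s in range(0, 900, 25)]
        indels = [make_indel(first_base=rng.randrange(1, 1000), vid=f"v{i}")
                  for i in range(60)]
        base = _find(peaks, indels)
        shuffled_peaks = peaks[:]
        rng.shuffle(shuffled_peaks)
        again = _find(shuffled_peaks, indels)
        assert [(r.indel.key, r.affected_peaks) for r in base] == \
               [(r.indel.key, r.affected_peaks) for r in again]


class TestAssignGenes:
    GENE_PLUS = GeneModel("gp", GenomicInterval("chr1", 10_000, 20_000), "+")

    def _assign(self, first_base, gene=GENE_PLUS, window=WINDOW_UPSTREAM):
        records = _find([make_peak(start=first_base - 5, end=first_base + 5)],
                        [make_indel(first_base=first_base)])
        assign_genes(records, [gene], window)
        return records[0].gene_assignments

    def test_adjacent_upstream_base(self):
        assert self._assign(9_999) == [(self.GENE_PLUS, WINDOW_UPSTREAM, -1)]

    def test_downstream_base_flanking_only(self):
        assert self._assign(10_001) == []
        assert self._assign(10_001, window=WINDOW_FLANKING) == \
            [(self.GENE_PLUS, WINDOW_FLANKING, 1)]

    def test_minus_strand_upstream_is_rightward(self):
        gene = GeneModel("gm", GenomicInterval("chr1", 2_000, 10_001), "-")  # tss 10 000
        assert self._assign(10_003, gene=gene) == [(gene, WINDOW_UPSTREAM, -3)]

    def test_one_indel_many_genes(self):
        g1 = GeneModel("g1", GenomicInterval("chr1", 10_500, 12_000), "+")
        g2 = GeneModel("g2", GenomicInterval("chr1", 9_000, 9_800), "-")  # tss 9 799
        records = _find([make_peak(start=9_995, end=10_005)],
                        [make_indel(first_base=10_000)])
        assign_genes(records, [g1, g2], WINDOW_UPSTREAM)
        assert {g.gene_id for g, _, _ in records[0].gene_assignments} == {"g1", "g2"}

    def test_narrowing_window_never_adds(self):
        rng = random.Random(3)
        genes = [GeneModel(f"g{i}", GenomicInterval("chr1", s, s + 5_000),
                           rng.choice("+-"))
                 for i, s in enumerate(range(10_000, 200_000, 12_000))]
        indels = [make_indel(first_base=rng.randrange(1_000, 210_000), vid=f"v{i}")
                  for i in range(150)]
        peaks = [make_peak(start=max(1, v.first_affected_base() - 2),
                           end=v.first_affected_base() + 2) for v in indels]
        up = _find(peaks, indels)
        assign_genes(up, genes, WINDOW_UPSTREAM)
        flank = _find(peaks, indels)
        assign_genes(flank, genes, WINDOW_FLANKING)
        # both windows reach at most 5 kb / 2.5 kb: every flanking-upstream
        # assignment within 2.5 kb upstream must also appear in the 5 kb window
        up_pairs = {(r.indel.key, g.gene_id, d) for r in up
                    for g, _, d in r.gene_assignments}
        for r in flank:
            for g, _, d in r.gene_assignments:
                if -2_500 < d <= 0:
                    assert (r.indel.key, g.gene_id, d) in up_pairs

    def test_strand_reflection_oracle(self):
        # mirror the whole locus around position M: a minus-strand gene's
        # assignments must equal the plus-strand assignments of the mirror
        M = 50_000
        gene_p = GeneModel("g", GenomicInterval("chr1", 10_000, 20_000), "+")
        gene_m = GeneModel("g", GenomicInterval("chr1", M - 20_000, M - 10_000 + 1), "-")
        assert gene_m.tss == M - gene_p.tss
        for b in (9_999, 9_000, 5_001, 10_000, 10_001, 12_000):
            d_p = signed_tss_distance(b, gene_p)
            d_m = signed_tss_distance(M - b, gene_m)
            assert d_p == d_m


class TestSummarize:
    def test_redundancy_counts(self):
        peaks = [make_peak(start=90, end=120, tf="A"),
                 make_peak(start=95, end=125, tf="B"),
                 make_peak(start=100, end=130, tf="C")]
        records = _find(peaks, [make_indel(first_base=105)])
        s = summarize(records)
        assert (s.n_tfbs_affected, s.n_unique_indels) == (3, 1)
        assert s.mean_tfbs_per_indel == 3.0
        assert s.per_tf_counts == {"A": 1, "B": 1, "C": 1}

    def test_empty_input_zero_summary(self):
        s = summarize([])
        assert (s.n_tfbs_affected, s.n_unique_indels, s.mean_tfbs_per_indel) == (0, 0, 0.0)

    def test_mean_is_exact_ratio(self):
        s = OverlapSummary(n_tfbs_affected=7, n_unique_indels=2)
        assert s.mean_tfbs_per_indel == 3.5

    def test_histogram_matches_hand_tally(self):
        gene = GeneModel("g", GenomicInterval("chr1", 10_000, 20_000), "+")
        bases = [9_999, 9_998, 7_500, 5_001, 10_000]  # distances -1,-2,-2500,-4999,0
        indels = [make_indel(first_base=b, vid=f"v{i}") for i, b in enumerate(bases)]
        peaks = [make_peak(start=b - 1, end=b + 1) for b in bases]
        records = _find(peaks, indels)
        assign_genes(records, [gene], WINDOW_UPSTREAM)
        s = summarize(records, n_bins=5)
        edges, counts = s.position_histogram[WINDOW_UPSTREAM]
        assert edges == [-5000, -4000, -3000, -2000, -1000, 0]
        # -4999 -> first bin; -2500 -> third; -1, -2, 0 -> last
        assert counts == [1, 0, 1, 0, 3]


def test_window_membership_boundaries():
    assert in_window(0, WINDOW_UPSTREAM)
    assert in_window(-4_999, WINDOW_UPSTREAM)
    assert not in_window(-5_000, WINDOW_UPSTREAM)
    assert not in_window(1, WINDOW_UPSTREAM)
    assert in_window(2_499, WINDOW_FLANKING)
    assert in_window(-2_499, WINDOW_FLANKING)
    assert not in_window(2_500, WINDOW_FLANKING)
    assert not in_window(-2_500, WINDOW_FLANKING)
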