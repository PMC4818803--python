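"""Matched regions: overlap grouping oracle, fold arithmetic, binomial test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chipdiff.diffmod import (
    FragmentIndex,
    MatchedRegion,
    fold_change,
    match_peaks,
    region_counts,
    region_difference_test,
    score_regions,
    select_top_regions,
)
from chipdiff.genomic import GenomicInterval, TagCollection
from chipdiff.peakcall import Peak


def peak(chrom, start, end):
    return Peak(GenomicInterval(chrom, start, end), 0, 0.0, 1.0)


def peaks(spec):
    return [peak(c, s, e) for c, s, e in spec]


def match_peaks_oracle(control, treated):
    """O(n^2) connected components over the interval-overlap graph."""
    nodes = [(p.interval, "c") for p in control] + [(p.interval, "t") for p in treated]
    n = len(nodes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i][0], nodes[j][0]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        ivs = [nodes[i][0] for i in members]
        sources = {nodes[i][1] for i in members}
        out.append(
            (
                ivs[0].chrom,
                min(iv.start for iv in ivs),
                max(iv.end for iv in ivs),
                "c" in sources,
                "t" in sources,
            )
        )
    return sorted(out)


def random_disjoint_peaks(rng, n, chrom="chr1"):
    widths = rng.integers(1, 50, size=n)
    out = []
    pos = 0
    for gap, w in zip(rng.integers(0, 60, size=n), widths):
        pos += gap
        out.append(peak(chrom, int(pos), int(pos + w)))
        pos += int(w)
    return out


class TestMatchPeaks:
    def test_overlapping_pair_merges_to_union(self):
        regions = match_peaks(
            peaks([("chr1", 100, 200)]), peaks([("chr1", 150, 250)])
        )
        (r,) = regions
        assert (r.interval.start, r.interval.end) == (100, 250)
        assert r.in_control and r.in_treated

    def test_disjoint_peaks_stay_single_source(self):
        regions = match_peaks(
            peaks([("chr1", 0, 100)]), peaks([("chr1", 200, 300)])
        )
        assert len(regions) == 2
        assert regions[0].in_control and not regions[0].in_treated
        assert regions[1].in_treated and not regions[1].in_control

    def test_transitive_chain_joins_three_peaks(self):
        regions = match_peaks(
            peaks([("chr1", 0, 100), ("chr1", 105, 200)]),
            peaks([("chr1", 90, 110)]),
        )
        (r,) = regions
        assert (r.interval.start, r.interval.end) == (0, 200)
        assert r.in_control and r.in_treated

    def test_abutting_peaks_do_not_merge(self):
        regions = match_peaks(
            peaks([("chr1", 0, 100)]), peaks([("chr1", 100, 200)])
        )
        assert len(regions) == 2

    def test_overlapping_within_one_list_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            match_peaks(peaks([("chr1", 0, 100), ("chr1", 50, 150)]), [])

    def test_unsorted_list_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            match_peaks(peaks([("chr1", 200, 300), ("chr1", 0, 100)]), [])

    @pytest.mark.parametrize("case_seed", range(25))
    def test_matches_brute_force_oracle(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        control = random_disjoint_peaks(rng, int(rng.integers(0, 40)))
        treated = random_disjoint_peaks(rng, int(rng.integers(0, 40)))
        got = sorted(
            (
                r.interval.chrom,
                r.interval.start,
                r.interval.end,
                r.in_control,
                r.in_treated,
            )
            for r in match_peaks(control, treated)
        )
        assert got == match_peaks_oracle(control, treated)


class TestFoldChange:
    def test_equal_counts_give_unit_fold(self):
        linear, l2 = fold_change(10, 10)
        assert linear == 1.0 and l2 == 0.0

    def test_pseudocounted_arithmetic(self):
        linear, l2 = fold_change(10, 20, pseudocount=1.0)
        assert linear == pytest.approx(21 / 11)
        assert l2 == pytest.approx(np.log2(21 / 11))

    def test_zero_counts_defined(self):
        linear, _ = fold_change(0, 0)
        assert linear == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1, 0)
        with pytest.raises(ValueError):
            fold_change(1, 1, pseudocount=0.0)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    def test_swap_negates_log2(self, a, b):
        _, l2_ab = fold_change(a, b)
        _, l2_ba = fold_change(b, a)
        assert l2_ab == pytest.approx(-l2_ba, abs=1e-12)


def binom_two_sided_oracle(k, n):
    """Exact two-sided binomial p at 1/2 via rational arithmetic."""
    pk = Fraction(comb(n, k), 2**n)
    total = sum(
        (Fraction(comb(n, j), 2**n) for j in range(n + 1)
         if Fraction(comb(n, j), 2**n) <= pk),
        Fraction(0),
    )
    return float(min(total, Fraction(1)))


class TestRegionDifferenceTest:
    def test_balanced_counts_give_one(self):
        assert region_difference_test(5, 5) == 1.0

    def test_hand_example_two_of_ten(self):
        # sum of P(X in {0,1,2,8,9,10}) for X ~ Bin(10, 1/2) = 112/1024
        assert region_difference_test(8, 2) == pytest.approx(112 / 1024, abs=1e-12)

    def test_extreme_counts(self):
        assert region_difference_test(30, 0) == pytest.approx(2 * 2.0**-30, abs=1e-15)

    def test_empty_region_gives_one(self):
        assert region_difference_test(0, 0) == 1.0

    @given(
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
    )
    def test_matches_rational_oracle_and_symmetry(self, a, b):
        p = region_difference_test(a, b)
        if a + b > 0:
            assert p == pytest.approx(binom_two_sided_oracle(b, a + b), abs=1e-12)
        assert p == pytest.approx(region_difference_test(b, a), abs=1e-12)


class TestFragmentIndex:
    def test_counts_fragment_overlap(self):
        # + tag at 100 -> fragment [100, 300); - tag at 500 -> [301, 501)
        tags = TagCollection.from_records([("chr1", 100, 1), ("chr1", 500, -1)])
        idx = FragmentIndex(tags, fragment_length=200)
        assert idx.count("chr1", 0, 100) == 0
        assert idx.count("chr1", 250, 350) == 2
        assert idx.count("chr1", 300, 301) == 0
        assert idx.count("chr2", 0, 1000) == 0

    def test_matches_naive_count(self, rng):
        tags = TagCollection.from_records(
            [("chr1", int(p), int(s)) for p, s in
             zip(rng.integers(0, 5000, 300), rng.choice([1, -1], 300))]
        )
        idx = FragmentIndex(tags, fragment_length=150)
        pos = tags.positions("chr1")
        strand = tags.strands("chr1")
        fstart = np.where(strand > 0, pos, pos - 149)
        fend = fstart + 150
        for start, end in [(0, 100), (1000, 1500), (4900, 5000), (2500, 2501)]:
            naive = int(np.sum((fstart < end) & (fend > start)))
            assert idx.count("chr1", start, end) == naive


class TestScoreAndSelect:
    def test_score_regions_fills_statistics(self):
        control = TagCollection.from_records([("chr1", 100, 1)] * 3)
        treated = TagCollection.from_records([("chr1", 100, 1)] * 9)
        region = MatchedRegion(GenomicInterval("chr1", 0, 400), True, True)
        (scored,) = score_regions([region], control, treated, fragment_length=200)
        assert (scored.count_control, scored.count_treated) == (3, 9)
        assert scored.fold_change == pytest.approx(10 / 4)
        assert scored.pvalue == pytest.approx(binom_two_sided_oracle(9, 12), abs=1e-12)
        assert scored.qvalue == pytest.approx(scored.pvalue)

    def test_select_top_filters_and_ranks(self):
        def region(start, p, l2):
            return MatchedRegion(
                GenomicInterval("chr1", start, start + 100),
                True, True, 1, 1, 2.0**l2, l2, p,
            )

        regions = [
            region(0, 0.01, 1.0),
            region(100, 0.04, 2.0),
            region(200, 0.20, 3.0),
            region(300, 0.001, 0.5),
            region(400, 0.04, 1.0),
        ]
        top = select_top_regions(regions, alpha=0.05, n_top=10)
        assert [r.interval.start for r in top] == [300, 0, 100, 400]
        top2 = select_top_regions(regions, alpha=0.05, n_top=2)
        assert [r.interval.start for r in top2] == [300, 0]

    def test_select_top_direction_filter(self):
        up = MatchedRegion(GenomicInterval("chr1", 0, 100), True, True,
                           1, 5, 3.0, 1.58, 0.01)
        down = MatchedRegion(GenomicInterval("chr1", 200, 300), True, True,
                             5, 1, 0.33, -1.58, 0.01)
        assert select_top_regions([up, down], direction="up") == [up]
        assert select_top_regions([up, down], direction="down") == [down]
        with pytest.raises(ValueError):
            select_top_regions([up], direction="sideways")

    def test_region_counts_wrapper(self):
        control = TagCollection.from_records([("chr1", 100, 1)] * 3)
        treated = TagCollection.from_records([("chr1", 100, 1)] * 6)
        iv = GenomicInterval("chr1", 0, 400)
        assert region_counts(iv, control, treated, fragment_length=200) == (3, 6)
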