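"""Peak caller: Poisson tail oracle, window counting, merging, equivariance."""

import math

import numpy as np
import pytest

from chipdiff.genomic import GenomeLayout, TagCollection
from chipdiff.peakcall import (
    PeakCallParams,
    call_peaks,
    extend_and_count,
    poisson_sf,
    score_windows,
)


def poisson_sf_oracle(count, lam):
    """Direct upper-tail series summation, independent of scipy."""
    if count == 0:
        return 1.0
    term = math.exp(-lam) * lam**count / math.factorial(count)
    total = 0.0
    j = count
    while term > total * 1e-18 or j == count:
        total += term
        j += 1
        term *= lam / j
        if term < 1e-320:
            break
    return total


def tags_at(positions, strand=1, chrom="chr1"):
    return TagCollection.from_records([(chrom, p, strand) for p in positions])


class TestPoissonSf:
    @pytest.mark.parametrize("count", [0, 1, 2, 5, 12, 25])
    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0, 3.5, 10.0])
    def test_matches_series_oracle(self, count, lam):
        assert poisson_sf(count, lam) == pytest.approx(
            poisson_sf_oracle(count, lam), abs=1e-12
        )

    def test_count_zero_is_one(self):
        assert poisson_sf(0, 5.0) == 1.0

    def test_monotone_decreasing_in_count(self):
        p = [poisson_sf(c, 3.0) for c in range(15)]
        assert all(a >= b for a, b in zip(p, p[1:]))

    def test_monotone_increasing_in_lambda(self):
        p = [poisson_sf(6, lam) for lam in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a < b for a, b in zip(p, p[1:]))

    def test_array_input(self):
        out = poisson_sf(np.array([0, 3]), np.array([1.0, 1.0]))
        assert out.shape == (2,)
        assert out[0] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_sf(3, 0.0)
        with pytest.raises(ValueError):
            poisson_sf(-1, 1.0)


class TestExtendAndCount:
    LAYOUT = GenomeLayout({"chr1": 400})
    PARAMS = PeakCallParams(window_size=100, fragment_length=200)

    def test_plus_tag_spans_three_windows(self):
        # + tag at 10 extends to [10, 210): windows 0, 1, 2
        counts = extend_and_count(tags_at([10]), self.LAYOUT, self.PARAMS)
        assert counts["chr1"].tolist() == [1, 1, 1, 0]

    def test_minus_tag_extends_leftward(self):
        # - tag 5' at 149 extends to [-50, 150), clipped to [0, 150)
        counts = extend_and_count(tags_at([149], strand=-1), self.LAYOUT, self.PARAMS)
        assert counts["chr1"].tolist() == [1, 1, 0, 0]

    def test_no_tags_gives_zeros(self):
        counts = extend_and_count(
            TagCollection.from_records([]), self.LAYOUT, self.PARAMS
        )
        assert counts["chr1"].tolist() == [0, 0, 0, 0]

    def test_counts_sum_to_window_overlap_events(self):
        rng = np.random.default_rng(0)
        tags = tags_at(rng.integers(0, 400, size=50).tolist())
        counts = extend_and_count(tags, self.LAYOUT, self.PARAMS)
        # each 200 bp fragment overlaps 2 or 3 100 bp windows unless clipped
        assert counts["chr1"].sum() >= 50

    def test_partial_last_window(self):
        layout = GenomeLayout({"chr1": 250})
        counts = extend_and_count(tags_at([240]), layout, self.PARAMS)
        assert len(counts["chr1"]) == 3
        assert counts["chr1"].tolist() == [0, 0, 1]


class TestScoreWindows:
    def test_empty_input_rejected(self):
        layout = GenomeLayout({"chr1": 400})
        with pytest.raises(ValueError, match="input sample is empty"):
            score_windows(tags_at([10]), TagCollection.from_records([]), layout)

    def test_lambda_is_max_of_three_terms(self):
        layout = GenomeLayout({"chr1": 400})
        params = PeakCallParams(
            window_size=100, fragment_length=1, min_background_lambda=0.1
        )
        treat = tags_at([150, 250, 250, 250])  # counts [0, 1, 3, 0]
        inp = tags_at([50, 150, 250, 350])  # counts [1, 1, 1, 1]
        windows = score_windows(treat, inp, layout, params)["chr1"]
        # depth ratio 4/4 = 1, genome rate 4/400 * 100 = 1 -> lambda = max(1,1,.1)
        assert [w.lambda_expected for w in windows] == [1.0, 1.0, 1.0, 1.0]
        assert windows[2].treat_count == 3
        assert windows[2].pvalue == pytest.approx(poisson_sf_oracle(3, 1.0), abs=1e-12)


class TestCallPeaks:
    def test_single_significant_window_becomes_peak(self):
        layout = GenomeLayout({"chr1": 400})
        params = PeakCallParams(window_size=100, fragment_length=1)
        # treat window counts [0, 1, 12, 1]; input 1 per window
        treat = tags_at([150] + [250] * 12 + [350])
        inp = tags_at([50, 150, 250, 350])
        peaks = call_peaks(treat, inp, layout, params)
        # lambda = max(1 * 14/4, 14/400*100, ...) = 3.5 everywhere
        assert len(peaks) == 1
        (peak,) = peaks
        assert (peak.interval.start, peak.interval.end) == (200, 300)
        assert peak.tag_count == 12
        assert peak.best_pvalue == pytest.approx(
            poisson_sf_oracle(12, 3.5), abs=1e-12
        )
        assert peak.best_pvalue < 0.05

    def test_windows_within_merge_gap_merge(self):
        layout = GenomeLayout({"chr1": 500})
        params = PeakCallParams(
            window_size=100, fragment_length=1, min_background_lambda=1.0
        )
        # significant windows 0 and 2 separated by a 100 bp gap (== merge gap)
        treat = tags_at([50] * 12 + [250] * 12)
        inp = tags_at([50, 150, 250, 350, 450])
        merged = call_peaks(treat, inp, layout, params)
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (0, 300)
        assert merged[0].tag_count == 24

        params_nogap = PeakCallParams(
            window_size=100, fragment_length=1, min_background_lambda=1.0, merge_gap=0
        )
        split = call_peaks(treat, inp, layout, params_nogap)
        assert len(split) == 2

    def test_empty_treatment_gives_no_peaks(self):
        layout = GenomeLayout({"chr1": 400})
        assert call_peaks(TagCollection.from_records([]), tags_at([50]), layout) == []

    def test_translation_equivariance(self):
        """Shifting all tags by a window multiple shifts the peaks identically."""
        shift = 300
        params = PeakCallParams(
            window_size=100, fragment_length=1, min_background_lambda=5.0
        )
        treat_pos = [1005] * 15 + [20_050, 40_050, 60_050]
        input_pos = [5_050, 15_050, 25_050, 35_050, 45_050, 55_050, 65_050, 75_050]
        base = call_peaks(
            tags_at(treat_pos),
            tags_at(input_pos),
            GenomeLayout({"chr1": 100_000}),
            params,
        )
        shifted = call_peaks(
            tags_at([p + shift for p in treat_pos]),
            tags_at([p + shift for p in input_pos]),
            GenomeLayout({"chr1": 100_000 + shift}),
            params,
        )
        assert len(base) == len(shifted) >= 1
        for b, s in zip(base, shifted):
            assert s.interval.start == b.interval.start + shift
            assert s.interval.end == b.interval.end + shift
            assert s.tag_count == b.tag_count

    def test_peaks_are_sorted_window_aligned_disjoint(self):
        rng = np.random.default_rng(42)
        layout = GenomeLayout({"chr1": 50_000, "chr2": 50_000})
        records = []
        for chrom in ("chr1", "chr2"):
            bg = rng.integers(0, 50_000, size=500)
            records += [(chrom, int(p), 1) for p in bg]
            # a dense cluster to guarantee at least one peak
            records += [(chrom, int(p), 1) for p in rng.integers(9000, 9300, size=120)]
        treat = TagCollection.from_records(records)
        inp = TagCollection.from_records(
            [("chr1", int(p), 1) for p in rng.integers(0, 50_000, size=500)]
            + [("chr2", int(p), 1) for p in rng.integers(0, 50_000, size=500)]
        )
        params = PeakCallParams()
        peaks = call_peaks(treat, inp, layout, params)
        assert peaks
        prev = None
        for p in peaks:
            assert p.interval.start % params.window_size == 0
            assert p.best_pvalue < params.alpha
            if prev and prev.interval.chrom == p.interval.chrom:
                assert p.interval.start > prev.interval.end
            prev = p


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PeakCallParams(window_size=-5)
        with pytest.raises(ValueError):
            PeakCallParams(alpha=1.5)
        with pytest.raises(ValueError):
            PeakCallParams(fragment_length=0)

    def test_merge_gap_defaults_to_window(self):
        assert PeakCallParams(window_size=100).effective_merge_gap == 100
        assert PeakCallParams(window_size=100, merge_gap=0).effective_merge_gap == 0
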