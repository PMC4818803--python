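"""Differential comparison of two conditions' peak lists.

Peaks from the control and treated ChIP samples are matched by genomic
overlap: peaks that overlap across (or within a transitive chain between)
the two lists are grouped and replaced by their union extent; peaks with no
cross-list overlap are kept as single-source regions, since outright gain or
loss of a peak is the strongest form of alteration.  For every matched
region the (depth-normalized) tag counts of both conditions are re-counted
over the union extent, a pseudocounted fold change is computed, and an exact
conditional binomial test provides the per-region p-value: given the total
count ``n = count_control + count_treated`` of two equal-depth Poisson
samples, the treated count is Binomial(n, 1/2) under the null of no change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log2
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from chipdiff._stats import bh_adjust
from chipdiff.genomic import GenomicInterval, TagCollection
from chipdiff.peakcall import Peak

__all__ = [
    "MatchedRegion",
    "FragmentIndex",
    "match_peaks",
    "region_counts",
    "fold_change",
    "region_difference_test",
    "score_regions",
    "select_top_regions",
]


@dataclass(frozen=True)
class MatchedRegion:
    """Union extent of overlap-matched peaks with differential statistics."""

    interval: GenomicInterval
    in_control: bool
    in_treated: bool
    count_control: int = 0
    count_treated: int = 0
    fold_change: float = 1.0
    log2_fold: float = 0.0
    pvalue: float = 1.0
    qvalue: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.in_control or self.in_treated):
            raise ValueError("a matched region must derive from at least one peak list")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive (pseudocounted)")

    @property
    def direction(self) -> str:
        return "up" if self.log2_fold >= 0 else "down"


class FragmentIndex:
    """Sorted extended-fragment boundaries for fast region overlap counting."""

    def __init__(self, tags: TagCollection, fragment_length: int):
        if fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom in tags.chromosomes():
            pos = tags.positions(chrom)
            strand = tags.strands(chrom)
            start = np.where(strand > 0, pos, pos - fragment_length + 1)
            end = start + fragment_length
            self._starts[chrom] = np.sort(start)
            self._ends[chrom] = np.sort(end)

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of fragments overlapping [start, end)."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        n_start_before_end = int(np.searchsorted(starts, end, side="left"))
        n_end_before_start = int(np.searchsorted(ends, start, side="right"))
        return n_start_before_end - n_end_before_start


def _check_sorted_disjoint(peaks: Sequence[Peak], label: str) -> None:
    prev: Optional[GenomicInterval] = None
    for p in peaks:
        iv = p.interval
        if prev is not None and prev.chrom == iv.chrom:
            if iv.start < prev.start:
                raise ValueError(f"{label} peak list is not sorted")
            if iv.start < prev.end:
                raise ValueError(f"{label} peak list contains overlapping peaks")
        prev = iv


def match_peaks(
    peaks_control: Sequence[Peak], peaks_treated: Sequence[Peak]
) -> List[MatchedRegion]:
    """Group peaks across the two lists by transitive genomic overlap.

    Each group becomes one region spanning the union extent, flagged by which
    condition(s) contributed peaks.  Both inputs must be sorted and
    internally non-overlapping.
    """
    _check_sorted_disjoint(peaks_control, "control")
    _check_sorted_disjoint(peaks_treated, "treated")
    events: List[Tuple[str, int, int, bool]] = [
        (p.interval.chrom, p.interval.start, p.interval.end, False)
        for p in peaks_control
    ] + [
        (p.interval.chrom, p.interval.start, p.interval.end, True)
        for p in peaks_treated
    ]
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    regions: List[MatchedRegion] = []
    cur: Optional[List] = None  # [chrom, start, end, in_control, in_treated]
    for chrom, start, end, is_treated in events:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3] = cur[3] or (not is_treated)
            cur[4] = cur[4] or is_treated
        else:
            if cur is not None:
                regions.append(
                    MatchedRegion(
                        GenomicInterval(cur[0], cur[1], cur[2]), cur[3], cur[4]
                    )
                )
            cur = [chrom, start, end, not is_treated, is_treated]
    if cur is not None:
        regions.append(
            MatchedRegion(GenomicInterval(cur[0], cur[1], cur[2]), cur[3], cur[4])
        )
    return regions


def region_counts(
    region: MatchedRegion | GenomicInterval,
    tags_control: TagCollection,
    tags_treated: TagCollection,
    fragment_length: int = 200,
) -> Tuple[int, int]:
    """Extended-fragment overlap counts over the region extent, per condition."""
    iv = region.interval if isinstance(region, MatchedRegion) else region
    idx_c = FragmentIndex(tags_control, fragment_length)
    idx_t = FragmentIndex(tags_treated, fragment_length)
    return (
        idx_c.count(iv.chrom, iv.start, iv.end),
        idx_t.count(iv.chrom, iv.start, iv.end),
    )


def fold_change(
    count_control: int, count_treated: int, pseudocount: float = 1.0
) -> Tuple[float, float]:
    """Pseudocounted linear and log2 fold change, treated over control."""
    if count_control < 0 or count_treated < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    linear = (count_treated + pseudocount) / (count_control + pseudocount)
    return linear, log2(linear)


def region_difference_test(count_control: int, count_treated: int) -> float:
    """Two-sided exact binomial test of the treated count at null proportion 1/2.

    Conditional on ``n = count_control + count_treated`` from two
    depth-matched Poisson samples; returns 1.0 when n = 0.
    """
    if count_control < 0 or count_treated < 0:
        raise ValueError("counts must be non-negative")
    n = count_control + count_treated
    if n == 0:
        return 1.0
    return float(stats.binomtest(count_treated, n, 0.5).pvalue)


def score_regions(
    regions: Sequence[MatchedRegion],
    tags_control: TagCollection,
    tags_treated: TagCollection,
    fragment_length: int = 200,
    pseudocount: float = 1.0,
) -> List[MatchedRegion]:
    """Fill counts, fold change, p- and BH q-values for matched regions.

    The tag collections must already be depth-normalized (equal totals).
    """
    idx_c = FragmentIndex(tags_control, fragment_length)
    idx_t = FragmentIndex(tags_treated, fragment_length)
    scored: List[MatchedRegion] = []
    for r in regions:
        iv = r.interval
        cc = idx_c.count(iv.chrom, iv.start, iv.end)
        ct = idx_t.count(iv.chrom, iv.start, iv.end)
        linear, l2 = fold_change(cc, ct, pseudocount)
        p = region_difference_test(cc, ct)
        scored.append(
            replace(
                r,
                count_control=cc,
                count_treated=ct,
                fold_change=linear,
                log2_fold=l2,
                pvalue=p,
            )
        )
    if scored:
        qs = bh_adjust(np.array([r.pvalue for r in scored]))
        scored = [replace(r, qvalue=float(q)) for r, q in zip(scored, qs)]
    return scored


def select_top_regions(
    regions: Sequence[MatchedRegion],
    alpha: float = 0.05,
    n_top: int = 2000,
    direction: Optional[str] = None,
) -> List[MatchedRegion]:
    """Significant regions ranked by p (ties: |log2 fold| desc, then position).

    Filters to ``pvalue < alpha`` (and to ``direction`` if given), then
    truncates to the top ``n_top``.
    """
    if direction not in (None, "up", "down"):
        raise ValueError("direction must be None, 'up' or 'down'")
    kept = [
        r
        for r in regions
        if r.pvalue < alpha and (direction is None or r.direction == direction)
    ]
    kept.sort(
        key=lambda r: (
            r.pvalue,
            -abs(r.log2_fold),
            r.interval.chrom,
            r.interval.start,
        )
    )
    return kept[:n_top]
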