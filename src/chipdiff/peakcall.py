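"""Windowed two-sample Poisson peak detection against an input control.

Each tag is extended ``fragment_length`` bp 3'-ward from its 5' end into the
fragment it represents; the genome is tiled with fixed non-overlapping
windows (default 100 bp) and a window's count is the number of extended
fragments overlapping it.  The expected count of a window is the maximum of
three terms: the depth-scaled input count for that window, the genome-wide
average window count of the ChIP sample, and a configurable floor.  Windows
whose upper Poisson tail probability falls below the threshold (default
0.05) are kept and runs of kept windows separated by at most ``merge_gap``
bp are merged into peaks.

The caller is a deliberately simplified re-implementation of the classic
two-sample model: no fragment-size estimation from strand cross-correlation,
no multi-scale local lambda, no duplicate filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from chipdiff._stats import bh_adjust
from chipdiff.genomic import GenomeLayout, GenomicInterval, TagCollection

__all__ = [
    "PeakCallParams",
    "Window",
    "Peak",
    "extend_and_count",
    "poisson_sf",
    "score_windows",
    "call_peaks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakCallParams:
    """Window size and threshold default to 100 bp and p < 0.05; the default
    fragment length (200 bp) is the midpoint of the 100-300 bp sonication
    range typical of the assay."""

    window_size: int = 100
    alpha: float = 0.05
    fragment_length: int = 200
    merge_gap: Optional[int] = None  # None -> window_size
    min_background_lambda: float = 0.1

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        if self.merge_gap is not None and self.merge_gap < 0:
            raise ValueError("merge_gap must be non-negative")
        if self.min_background_lambda < 0:
            raise ValueError("min_background_lambda must be non-negative")

    @property
    def effective_merge_gap(self) -> int:
        return self.window_size if self.merge_gap is None else self.merge_gap


@dataclass(frozen=True)
class Window:
    """A scored genomic window in the two-sample comparison."""

    interval: GenomicInterval
    treat_count: int
    input_count: int
    lambda_expected: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.treat_count < 0 or self.input_count < 0:
            raise ValueError("window counts must be non-negative")
        if not (0 <= self.pvalue <= 1):
            raise ValueError("pvalue must lie in [0, 1]")


@dataclass(frozen=True)
class Peak:
    """A run of significant windows merged into one enriched region."""

    interval: GenomicInterval
    tag_count: int
    best_pvalue: float
    fold_vs_input: float
    qvalue: float = float("nan")


def _fragment_bounds(
    tags: TagCollection, chrom: str, fragment_length: int, chrom_len: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Extended-fragment [start, end) arrays, clipped to the chromosome."""
    pos = tags.positions(chrom)
    strand = tags.strands(chrom)
    start = np.where(strand > 0, pos, pos - fragment_length + 1)
    end = start + fragment_length
    n_outside = int(np.count_nonzero((pos < 0) | (pos >= chrom_len)))
    if n_outside:
        logger.warning(
            "%d tags beyond the end of %s were clipped", n_outside, chrom
        )
    start = np.clip(start, 0, chrom_len)
    end = np.clip(end, 0, chrom_len)
    ok = end > start
    return start[ok], end[ok]


def _window_widths(chrom_len: int, window: int) -> np.ndarray:
    n_win = -(-chrom_len // window)  # ceil
    widths = np.full(n_win, window, dtype=np.int64)
    rem = chrom_len - (n_win - 1) * window
    widths[-1] = rem
    return widths


def extend_and_count(
    tags: TagCollection, layout: GenomeLayout, params: PeakCallParams
) -> Dict[str, np.ndarray]:
    """Per-chromosome window counts of extended-fragment overlap events.

    A fragment overlapping k windows contributes 1 to each, so the counts sum
    to at least the number of tags.
    """
    counts: Dict[str, np.ndarray] = {}
    w = params.window_size
    for chrom in layout:
        chrom_len = layout[chrom]
        n_win = -(-chrom_len // w)
        fstart, fend = _fragment_bounds(tags, chrom, params.fragment_length, chrom_len)
        diff = np.zeros(n_win + 1, dtype=np.int64)
        if len(fstart):
            first = fstart // w
            last = (fend - 1) // w
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
        counts[chrom] = np.cumsum(diff)[:n_win]
    return counts


def poisson_sf(count, lam):
    """Upper-tail Poisson probability P(X >= count) for X ~ Poisson(lam).

    Accepts scalars or arrays; ``lam`` must be positive.
    """
    count_arr = np.asarray(count)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be positive")
    if np.any(count_arr < 0):
        raise ValueError("count must be non-negative")
    p = stats.poisson.sf(count_arr - 1, lam_arr)
    if np.isscalar(count) and np.isscalar(lam):
        return float(p)
    return p


def score_windows(
    treat: TagCollection,
    control_input: TagCollection,
    layout: GenomeLayout,
    params: PeakCallParams = PeakCallParams(),
) -> Dict[str, List[Window]]:
    """Score every genome window of the ChIP sample against its input.

    The expectation for a window of width ``w`` is
    ``max(input_count * depth_ratio, genome_rate * w, floor * w / window)``
    where ``depth_ratio`` is ChIP total over input total and ``genome_rate``
    is the ChIP sample's average window count per bp.
    """
    if control_input.total_tags == 0:
        raise ValueError("input sample is empty: no background expectation")
    treat_counts = extend_and_count(treat, layout, params)
    input_counts = extend_and_count(control_input, layout, params)
    depth_ratio = treat.total_tags / control_input.total_tags

    total_count = sum(int(c.sum()) for c in treat_counts.values())
    total_width = layout.total_size
    genome_rate = total_count / total_width  # overlap events per bp

    out: Dict[str, List[Window]] = {}
    w = params.window_size
    for chrom in layout:
        widths = _window_widths(layout[chrom], w)
        tc = treat_counts[chrom]
        ic = input_counts[chrom]
        lam = np.maximum.reduce(
            [
                ic * depth_ratio,
                genome_rate * widths,
                params.min_background_lambda * widths / w,
            ]
        )
        lam = np.maximum(lam, 1e-12)
        pvals = stats.poisson.sf(tc - 1, lam)
        starts = np.arange(len(widths), dtype=np.int64) * w
        out[chrom] = [
            Window(
                GenomicInterval(chrom, int(s), int(s + width)),
                int(c),
                int(i),
                float(l),
                float(p),
            )
            for s, width, c, i, l, p in zip(starts, widths, tc, ic, lam, pvals)
        ]
    return out


def call_peaks(
    treat: TagCollection,
    control_input: TagCollection,
    layout: GenomeLayout,
    params: PeakCallParams = PeakCallParams(),
) -> List[Peak]:
    """Two-sample peak calling: significant windows merged into peaks.

    Peaks are window-aligned, non-overlapping, sorted by (chromosome, start),
    and carry the summed window count, the minimum member p-value, the fold
    over the summed expectation, and a BH q-value (minimum over member
    windows of the genome-wide window-level adjustment).
    """
    if treat.total_tags == 0:
        if control_input.total_tags == 0:
            raise ValueError("input sample is empty: no background expectation")
        return []
    windows = score_windows(treat, control_input, layout, params)
    all_p = np.concatenate(
        [np.array([win.pvalue for win in ws]) for ws in windows.values()]
    )
    all_q = bh_adjust(all_p)
    gap = params.effective_merge_gap

    peaks: List[Peak] = []
    offset = 0
    for chrom in layout:
        ws = windows[chrom]
        qs = all_q[offset : offset + len(ws)]
        offset += len(ws)
        sig = [(win, q) for win, q in zip(ws, qs) if win.pvalue < params.alpha]
        if not sig:
            continue
        group: List[Tuple[Window, float]] = [sig[0]]
        for win, q in sig[1:]:
            if win.interval.start - group[-1][0].interval.end <= gap:
                group.append((win, q))
            else:
                peaks.append(_merge_group(group))
                group = [(win, q)]
        peaks.append(_merge_group(group))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def _merge_group(group: List[Tuple["Window", float]]) -> Peak:
    wins = [w for w, _ in group]
    qs = [q for _, q in group]
    interval = GenomicInterval(
        wins[0].interval.chrom, wins[0].interval.start, wins[-1].interval.end
    )
    tag_count = int(sum(w.treat_count for w in wins))
    lam_sum = float(sum(w.lambda_expected for w in wins))
    return Peak(
        interval=interval,
        tag_count=tag_count,
        best_pvalue=float(min(w.pvalue for w in wins)),
        fold_vs_input=tag_count / lam_sum if lam_sum > 0 else float("inf"),
        qvalue=float(min(qs)),
    )
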