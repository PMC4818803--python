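"""Assignment of matched regions to genes through a +/-2 kb TSS window.

A region qualifies a gene when it overlaps the closed window of 2,000 bp on
either side of the gene's transcription start site (the window is symmetric
regardless of strand).  A region may qualify several genes and a gene may be
hit by several regions; the gene-level table keeps, per gene, the region
with the smallest p-value (ties: smallest TSS distance, then leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from chipdiff._stats import bh_adjust
from chipdiff.diffmod import MatchedRegion
from chipdiff.genomic import GeneModel

__all__ = ["PromoterAssignment", "assign_regions_to_genes", "gene_level_table"]

DEFAULT_PROMOTER_WINDOW = 2000


@dataclass(frozen=True)
class PromoterAssignment:
    """One (gene, region) link within the promoter window."""

    gene: GeneModel
    region: MatchedRegion
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def _tss_distance(region: MatchedRegion, tss: int) -> int:
    iv = region.interval
    if iv.start <= tss < iv.end:
        return 0
    return min(abs(iv.start - tss), abs(iv.end - 1 - tss))


def assign_regions_to_genes(
    regions: Sequence[MatchedRegion],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_PROMOTER_WINDOW,
) -> List[PromoterAssignment]:
    """All (gene, region) pairs whose region lies within ``window`` bp of the TSS.

    "Within 2,000 bp" is inclusive: a region whose nearest base is exactly
    ``window`` bp from the TSS qualifies.  The distance is 0 when the region
    covers the TSS, otherwise the distance from the TSS to the nearest region
    base.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arrays = {
        c: (
            np.array([g.tss for g in sorted(gs, key=lambda g: (g.tss, g.gene_id))]),
            sorted(gs, key=lambda g: (g.tss, g.gene_id)),
        )
        for c, gs in by_chrom.items()
    }
    out: List[PromoterAssignment] = []
    for region in regions:
        iv = region.interval
        entry = tss_arrays.get(iv.chrom)
        if entry is None:
            continue
        tss, gene_list = entry
        # overlap with [tss - window, tss + window + 1) <=>
        # tss in [start - window, end - 1 + window]
        lo = int(np.searchsorted(tss, iv.start - window, side="left"))
        hi = int(np.searchsorted(tss, iv.end - 1 + window, side="right"))
        for g in gene_list[lo:hi]:
            out.append(
                PromoterAssignment(g, region, _tss_distance(region, g.tss))
            )
    return out


def gene_level_table(assignments: Sequence[PromoterAssignment]) -> pd.DataFrame:
    """Collapse assignments to one representative region per gene.

    The representative is the assignment with the smallest region p-value,
    breaking ties by smallest TSS distance and then by leftmost region.
    Genes with no assignment are absent.  Columns: gene_id, chrom, tss,
    strand, region coordinates, normalized counts, fold change, log2 fold,
    p-value, BH q-value across the table, direction, distance.
    """
    best: Dict[str, PromoterAssignment] = {}
    for a in assignments:
        key = a.gene.gene_id
        cur = best.get(key)
        if cur is None or _rank(a) < _rank(cur):
            best[key] = a

    rows = []
    for gid in sorted(best):
        a = best[gid]
        r = a.region
        rows.append(
            {
                "gene_id": gid,
                "chrom": a.gene.chrom,
                "tss": a.gene.tss,
                "strand": a.gene.strand,
                "region_start": r.interval.start,
                "region_end": r.interval.end,
                "count_control": r.count_control,
                "count_treated": r.count_treated,
                "fold_change": r.fold_change,
                "log2_fold": r.log2_fold,
                "pvalue": r.pvalue,
                "direction": r.direction,
                "distance": a.distance,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "tss",
            "strand",
            "region_start",
            "region_end",
            "count_control",
            "count_treated",
            "fold_change",
            "log2_fold",
            "pvalue",
            "direction",
            "distance",
        ],
    )
    if len(df):
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["qvalue"] = pd.Series(dtype=float)
    return df


def _rank(a: PromoterAssignment):
    return (
        a.region.pvalue,
        a.distance,
        a.region.interval.chrom,
        a.region.interval.start,
    )
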