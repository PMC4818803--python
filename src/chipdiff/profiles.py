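"""TSS tag-density profiles, heatmap matrices, qPCR arithmetic and recovery.

Profiles use the same extended-fragment overlap counting as the peak caller
so one counting definition holds across the whole analysis.  Rows of
minus-strand genes are reversed so matrix columns always read 5' to 3'
relative to transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from chipdiff.diffmod import FragmentIndex
from chipdiff.genomic import GeneModel, GenomeLayout, TagCollection
from chipdiff.peakcall import PeakCallParams, extend_and_count
from chipdiff.simulate import PromoterTruth

__all__ = [
    "tss_density_profile",
    "heatmap_matrix",
    "qpcr_fold_change",
    "RecoveryMetrics",
    "recovery_metrics",
    "write_density_bedgraph",
]


def tss_density_profile(
    tags: TagCollection,
    genes: Sequence[GeneModel],
    flank: int = 2000,
    bin_size: int = 50,
    fragment_length: int = 200,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Per-gene fragment-overlap counts in bins across [tss - flank, tss + flank).

    Returns the genes x bins integer matrix (index = gene ids, columns = bin
    start offsets relative to the TSS in transcription orientation) and the
    mean profile in overlap events per bin per million tags.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    index = FragmentIndex(tags, fragment_length)
    matrix = np.zeros((len(genes), n_bins), dtype=np.int64)
    for i, g in enumerate(genes):
        edges = g.tss - flank + bin_size * np.arange(n_bins + 1)
        row = np.array(
            [
                index.count(g.chrom, int(edges[j]), int(edges[j + 1]))
                for j in range(n_bins)
            ],
            dtype=np.int64,
        )
        if g.strand == "-":
            row = row[::-1]
        matrix[i] = row
    columns = (-flank + bin_size * np.arange(n_bins)).tolist()
    df = pd.DataFrame(matrix, index=[g.gene_id for g in genes], columns=columns)
    total = tags.total_tags
    scale = 1e6 / total if total else 0.0
    mean_profile = matrix.mean(axis=0) * scale if len(genes) else np.zeros(n_bins)
    return df, mean_profile


def heatmap_matrix(
    gene_table: pd.DataFrame, top_n: int = 2000, alpha: float = 0.05
) -> pd.DataFrame:
    """Ranked matrix of the top altered genes for heatmap export.

    Genes with p < alpha are ranked by ascending p (ties by |log2 fold|
    descending, then position) and truncated to ``top_n``; the returned frame
    carries the log2 fold plus both conditions' normalized promoter counts,
    in ranking order.
    """
    sig = gene_table[gene_table["pvalue"] < alpha].copy()
    sig["_abs_l2"] = sig["log2_fold"].abs()
    sig = sig.sort_values(
        ["pvalue", "_abs_l2", "chrom", "region_start"],
        ascending=[True, False, True, True],
        kind="stable",
    ).head(top_n)
    out = sig[
        ["gene_id", "direction", "log2_fold", "count_control", "count_treated", "pvalue"]
    ].reset_index(drop=True)
    return out


def qpcr_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative quantification by the delta-delta-Ct method: 2**(-ddCt)."""
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity_up: float
    sensitivity_down: float
    observed_fdr: float
    direction_accuracy: float
    n_reported_altered: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "sensitivity_up": self.sensitivity_up,
            "sensitivity_down": self.sensitivity_down,
            "observed_fdr": self.observed_fdr,
            "direction_accuracy": self.direction_accuracy,
            "n_reported_altered": self.n_reported_altered,
        }


def recovery_metrics(
    gene_table: pd.DataFrame, truth: PromoterTruth, alpha: float = 0.05
) -> RecoveryMetrics:
    """Truth-based recovery of the simulated promoter classes.

    A gene is *reported altered* when it appears in the gene table with
    p < alpha; it is *recovered* for its class when additionally the reported
    direction matches.  Observed FDR is the fraction of reported-altered
    genes whose truth class is unchanged (0 when nothing is reported);
    direction accuracy is evaluated over reported genes whose truth class is
    up or down (1.0 vacuously).
    """
    table_ids = set(gene_table["gene_id"]) if len(gene_table) else set()
    unknown = table_ids - set(truth.classes)
    if unknown:
        raise ValueError(f"gene ids absent from truth: {sorted(unknown)[:5]} ...")

    reported = (
        gene_table[gene_table["pvalue"] < alpha] if len(gene_table) else gene_table
    )
    reported_dir = dict(zip(reported["gene_id"], reported["direction"])) if len(
        reported
    ) else {}

    sens = {}
    for cls in ("up", "down"):
        truth_genes = truth.genes_in_class(cls)
        if truth_genes:
            hit = sum(1 for g in truth_genes if reported_dir.get(g) == cls)
            sens[cls] = hit / len(truth_genes)
        else:
            sens[cls] = 0.0

    n_reported = len(reported_dir)
    if n_reported:
        false_pos = sum(
            1 for g in reported_dir if truth.classes[g] == "unchanged"
        )
        fdr = false_pos / n_reported
    else:
        fdr = 0.0

    altered_reported = [
        g for g in reported_dir if truth.classes[g] in ("up", "down")
    ]
    if altered_reported:
        correct = sum(
            1 for g in altered_reported if reported_dir[g] == truth.classes[g]
        )
        direction_accuracy = correct / len(altered_reported)
    else:
        direction_accuracy = 1.0

    return RecoveryMetrics(
        sensitivity_up=sens["up"],
        sensitivity_down=sens["down"],
        observed_fdr=fdr,
        direction_accuracy=direction_accuracy,
        n_reported_altered=n_reported,
    )


def write_density_bedgraph(
    tags: TagCollection,
    layout: GenomeLayout,
    path: str | Path,
    window_size: int = 100,
    fragment_length: int = 200,
) -> None:
    """Genome-wide extended-fragment window density as a bedGraph track."""
    params = PeakCallParams(window_size=window_size, fragment_length=fragment_length)
    counts = extend_and_count(tags, layout, params)
    total = tags.total_tags
    scale = 1e6 / total if total else 0.0
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="tag_density"\n')
        for chrom in layout:
            c = counts[chrom]
            for i, v in enumerate(c):
                if v == 0:
                    continue
                start = i * window_size
                end = min(start + window_size, layout[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{v * scale:.4f}\n")
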