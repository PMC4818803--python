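#!/usr/bin/env python
"""Step 3: depth-normalize the ChIPs, match peaks, score regions, gene table."""

import json

import numpy as np
import pandas as pd

from chipdiff import diffmod, genomic, normalize, peakcall, promoters

from common import DIFF_DIR, PEAKS_DIR, RESULTS, SEED, SIM_DIR, ensure_dirs


def load_peaks(path):
    frame = pd.read_csv(path, sep="\t")
    return [
        peakcall.Peak(
            genomic.GenomicInterval(r.chrom, int(r.start), int(r.end)),
            int(r.tag_count), float(r.best_pvalue), float(r.fold_vs_input),
        )
        for r in frame.itertuples()
    ]


def main() -> None:
    ensure_dirs()
    control = genomic.read_tags_bed(SIM_DIR / "tags_control_chip.bed")
    treated = genomic.read_tags_bed(SIM_DIR / "tags_treated_chip.bed")
    sub_seed = int(np.random.SeedSequence([SEED, 101]).generate_state(1)[0] % 2**31)
    norm_control, norm_treated, ratio = normalize.normalize_pair(
        control, treated, sub_seed
    )

    peaks_c = load_peaks(PEAKS_DIR / "peaks_control.tsv")
    peaks_t = load_peaks(PEAKS_DIR / "peaks_treated.tsv")
    regions = diffmod.match_peaks(peaks_c, peaks_t)
    scored = diffmod.score_regions(regions, norm_control, norm_treated)

    rows = pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in scored],
            "start": [r.interval.start for r in scored],
            "end": [r.interval.end for r in scored],
            "in_control": [int(r.in_control) for r in scored],
            "in_treated": [int(r.in_treated) for r in scored],
            "count_control": [r.count_control for r in scored],
            "count_treated": [r.count_treated for r in scored],
            "log2_fold": [r.log2_fold for r in scored],
            "pvalue": [r.pvalue for r in scored],
            "qvalue": [r.qvalue for r in scored],
        }
    )
    rows.to_csv(DIFF_DIR / "regions.tsv", sep="\t", index=False, float_format="%.6g")

    genes = genomic.read_gene_annotation(SIM_DIR / "genes.tsv")
    matched = [r for r in scored if r.in_control and r.in_treated]
    assignments = promoters.assign_regions_to_genes(matched, genes, window=2000)
    gene_table = promoters.gene_level_table(assignments)
    gene_table.to_csv(DIFF_DIR / "gene_table.tsv", sep="\t", index=False,
                      float_format="%.6g")

    sig = gene_table[gene_table["pvalue"] < 0.05]
    for direction in ("up", "down"):
        ids = sig[sig["direction"] == direction]["gene_id"]
        (DIFF_DIR / f"genes_{direction}.txt").write_text(
            "".join(f"{g}\n" for g in ids)
        )

    summary = {
        "chip_depth_ratio": ratio,
        "normalized_depth": norm_control.total_tags,
        "subsample_seed": sub_seed,
        "n_regions": len(scored),
        "n_matched_both": len(matched),
        "n_genes_with_promoter_region": int(len(gene_table)),
        "n_genes_up": int((sig["direction"] == "up").sum()),
        "n_genes_down": int((sig["direction"] == "down").sum()),
    }
    with open(RESULTS / "03_differential.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
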