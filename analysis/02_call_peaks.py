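#!/usr/bin/env python
"""Step 2: window-based peak calling of each ChIP sample against its input."""

import json

import pandas as pd

from chipdiff import genomic, peakcall

from common import PEAKS_DIR, RESULTS, SIM_DIR, ensure_dirs


def main() -> None:
    ensure_dirs()
    layout = genomic.read_genome_tsv(SIM_DIR / "genome.tsv")
    params = peakcall.PeakCallParams()  # 100 bp windows, p < 0.05, 200 bp fragments

    summary = {"params": {"window_size": params.window_size, "alpha": params.alpha,
                          "fragment_length": params.fragment_length}}
    for cond in ("control", "treated"):
        chip = genomic.read_tags_bed(SIM_DIR / f"tags_{cond}_chip.bed")
        inp = genomic.read_tags_bed(SIM_DIR / f"tags_{cond}_input.bed")
        peaks = peakcall.call_peaks(chip, inp, layout, params)
        frame = pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in peaks],
                "start": [p.interval.start for p in peaks],
                "end": [p.interval.end for p in peaks],
                "tag_count": [p.tag_count for p in peaks],
                "fold_vs_input": [p.fold_vs_input for p in peaks],
                "best_pvalue": [p.best_pvalue for p in peaks],
                "qvalue": [p.qvalue for p in peaks],
            }
        )
        frame.to_csv(PEAKS_DIR / f"peaks_{cond}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        widths = frame["end"] - frame["start"]
        summary[cond] = {
            "n_peaks": len(peaks),
            "median_width": float(widths.median()) if len(peaks) else 0.0,
            "median_fold_vs_input": float(frame["fold_vs_input"].median())
            if len(peaks) else 0.0,
        }
    with open(RESULTS / "02_peaks.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
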