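#!/usr/bin/env python
"""Step 5: TSS density profiles, heatmap export and truth-based recovery."""

import json

import numpy as np
import pandas as pd

from chipdiff import genomic, normalize, profiles, simulate

from common import DIFF_DIR, RESULTS, SEED, SIM_DIR, ensure_dirs


def main() -> None:
    ensure_dirs()
    genes = genomic.read_gene_annotation(SIM_DIR / "genes.tsv")
    truth = simulate.read_truth_tsv(SIM_DIR / "truth.tsv")
    control = genomic.read_tags_bed(SIM_DIR / "tags_control_chip.bed")
    treated = genomic.read_tags_bed(SIM_DIR / "tags_treated_chip.bed")
    sub_seed = int(np.random.SeedSequence([SEED, 101]).generate_state(1)[0] % 2**31)
    norm_control, norm_treated, _ = normalize.normalize_pair(
        control, treated, sub_seed
    )

    flank, bin_size = 2000, 50
    _, prof_control = profiles.tss_density_profile(
        norm_control, genes, flank=flank, bin_size=bin_size
    )
    _, prof_treated = profiles.tss_density_profile(
        norm_treated, genes, flank=flank, bin_size=bin_size
    )
    offsets = [-flank + bin_size * i for i in range(2 * flank // bin_size)]
    pd.DataFrame(
        {"offset": offsets, "control": prof_control, "treated": prof_treated}
    ).to_csv(RESULTS / "05_tss_profile.tsv", sep="\t", index=False,
             float_format="%.6g")

    gene_table = pd.read_csv(DIFF_DIR / "gene_table.tsv", sep="\t")
    heat = profiles.heatmap_matrix(gene_table, top_n=2000, alpha=0.05)
    heat.to_csv(DIFF_DIR / "heatmap.tsv", sep="\t", index=False, float_format="%.6g")

    metrics = profiles.recovery_metrics(gene_table, truth, alpha=0.05)
    with open(RESULTS / "05_recovery.json", "w") as fh:
        json.dump(metrics.as_dict(), fh, indent=2, sort_keys=True)
    print(json.dumps(metrics.as_dict(), indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
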