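#!/usr/bin/env python
"""Step 1: generate the four-sample synthetic study (tags, genes, truth, terms)."""

import json

from chipdiff import enrich, genomic, simulate

from common import RESULTS, SEED, SIM_DIR, ensure_dirs


def main() -> None:
    ensure_dirs()
    cfg = simulate.SimulationConfig(seed=SEED)
    genes, truth = simulate.simulate_genes(cfg)
    samples = simulate.simulate_tags(cfg, genes, truth)
    terms, planted = simulate.simulate_term_annotation(cfg, genes, truth)

    genomic.write_gene_annotation(genes, SIM_DIR / "genes.tsv")
    simulate.write_truth_tsv(truth, SIM_DIR / "truth.tsv")
    enrich.write_gmt(terms, SIM_DIR / "terms.gmt")
    genomic.write_genome_tsv(cfg.genome, SIM_DIR / "genome.tsv")
    for name, tc in samples.as_dict().items():
        genomic.write_tags_bed(tc, SIM_DIR / f"tags_{name}.bed")

    summary = {
        "seed": SEED,
        "genome_size": cfg.genome.total_size,
        "n_genes": len(genes),
        "class_sizes": {
            cls: len(truth.genes_in_class(cls))
            for cls in ("up", "down", "unchanged")
        },
        "tag_totals": {n: tc.total_tags for n, tc in samples.as_dict().items()},
        "planted_term": planted,
    }
    with open(RESULTS / "01_simulation.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
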