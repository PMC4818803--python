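#!/usr/bin/env python
"""Step 4: term enrichment (EASE) of the up- and down-regulated gene lists."""

import json

import pandas as pd

from chipdiff import enrich

from common import DIFF_DIR, RESULTS, SIM_DIR, ensure_dirs


def main() -> None:
    ensure_dirs()
    terms = enrich.read_gmt(SIM_DIR / "terms.gmt")
    gene_table = pd.read_csv(DIFF_DIR / "gene_table.tsv", sep="\t")
    universe = set(gene_table["gene_id"])

    summary = {}
    top_rows = []
    for direction in ("up", "down"):
        gene_list = [
            line.strip()
            for line in open(DIFF_DIR / f"genes_{direction}.txt")
            if line.strip()
        ]
        table = enrich.enrich_terms(gene_list, terms, universe, method="ease")
        table.to_csv(DIFF_DIR / f"enrichment_{direction}.tsv", sep="\t",
                     index=False, float_format="%.6g")
        head = table.head(5).copy()
        head.insert(0, "direction", direction)
        top_rows.append(head)
        summary[direction] = {
            "n_genes": len(gene_list),
            "n_terms_tested": int(len(table)),
            "top_term": table.iloc[0]["term_id"] if len(table) else None,
            "top_term_pvalue": float(table.iloc[0]["pvalue"]) if len(table) else None,
        }
    pd.concat(top_rows, ignore_index=True).to_csv(
        RESULTS / "04_enrichment_top.tsv", sep="\t", index=False, float_format="%.6g"
    )
    with open(RESULTS / "04_enrichment.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
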