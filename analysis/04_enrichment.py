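#!/usr/bin/env python
"""Hypergeometric enrichment of each interactome against the annotation
collection, pooled across miRNAs and ranked by -log10(p).

Reads results/sim/ and the interactome tables from step 03; writes
enrichment_pooled.tsv to results/.
"""

import warnings
from pathlib import Path

import pandas as pd

from mirglia import enrich, pool_and_rank, read_expression_matrix, read_gmt, significance_line

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results"

ALPHA = 0.05
TOP_N = 15


def main() -> None:
    mrna = read_expression_matrix(SIM / "mrna_matrix.tsv", "mRNA")
    annotations = read_gmt(SIM / "networks.gmt", role="annotation")
    universe = frozenset(mrna.feature_ids)

    tables = []
    for path in sorted(OUT.glob("interactome_*.tsv")):
        inter = pd.read_csv(path, sep="\t")
        if inter.empty:
            continue
        mirna_id = inter["mirna_id"].iloc[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables.append(enrich(set(inter["gene_symbol"]), annotations, universe, mirna_id))

    pooled = pool_and_rank(tables, alpha=ALPHA, top_n=TOP_N)
    pooled.to_csv(OUT / "enrichment_pooled.tsv", sep="\t", index=False)
    line = significance_line(ALPHA)
    print(f"pooled ranking over {len(tables)} interactomes; "
          f"significance line -log10(p) = {line:.2f}")
    for _, row in pooled.head(5).iterrows():
        marker = "*" if row["neg_log10_p"] > line else " "
        print(f" {marker} {row['set_name']} ({row['mirna_id']}): "
              f"-log10(p) = {row['neg_log10_p']:.2f}, k = {row['k_overlap']}/{row['set_size']}")


if __name__ == "__main__":
    main()
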