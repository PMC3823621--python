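#!/usr/bin/env python
"""Differential expression for both activation contrasts (M1 vs M0,
M2a vs M0) on the simulated arrays, with the up/down count summary.

Reads results/sim/, writes per-contrast DE tables and de_summary.json to
results/.
"""

import json
from pathlib import Path

from mirglia import read_expression_matrix, read_sample_sheet, run_contrast, summarize_contrast

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results"

MRNA_P = 1e-4
MIRNA_P = 0.05


def main() -> None:
    mrna = read_expression_matrix(SIM / "mrna_matrix.tsv", "mRNA")
    mirna = read_expression_matrix(SIM / "mirna_matrix.tsv", "miRNA")
    sheet = read_sample_sheet(SIM / "samples.tsv")

    summary = {}
    for treated in ("M1", "M2a"):
        cname = f"{treated}_vs_M0"
        de_genes = run_contrast(mrna, sheet, treated, "M0")
        de_mirnas = run_contrast(mirna, sheet, treated, "M0")
        de_genes.to_csv(OUT / f"de_mrna_{cname}.tsv", sep="\t", index=False)
        de_mirnas.to_csv(OUT / f"de_mirna_{cname}.tsv", sep="\t", index=False)
        gs = summarize_contrast(de_genes, MRNA_P)
        ms = summarize_contrast(de_mirnas, MIRNA_P)
        summary[cname] = {
            "genes": gs.__dict__,
            "mirnas": ms.__dict__,
        }
        print(f"{cname}: {gs.n_significant}/{gs.n_tested} genes at p<{MRNA_P:g} "
              f"({gs.n_up} up, {gs.n_down} down); "
              f"{ms.n_significant}/{ms.n_tested} miRNAs at p<{MIRNA_P:g} "
              f"({ms.n_up} up, {ms.n_down} down)")
        top = de_genes.nlargest(3, "linear_fold")[["feature_id", "linear_fold", "p_value"]]
        for _, row in top.iterrows():
            print(f"  top up gene {row['feature_id']}: {row['linear_fold']:.1f}-fold, "
                  f"p={row['p_value']:.2g}")

    (OUT / "de_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"summary written to {OUT / 'de_summary.json'}")


if __name__ == "__main__":
    main()
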