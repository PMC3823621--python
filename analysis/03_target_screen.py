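#!/usr/bin/env python
"""Correlation screen and dual-database intersection for every shortlisted
miRNA of the M1 contrast: the interactome-construction step.

Reads results/sim/ and the DE tables from step 02; writes per-miRNA
interactome tables and overlap_stats.tsv to results/.
"""

import warnings
from pathlib import Path

import pandas as pd

from mirglia import (
    build_interactome,
    classify_directions,
    correlate_mirna_genes,
    filter_candidates,
    intersect_targets,
    overlap_fractions,
    read_expression_matrix,
    read_gmt,
    read_sample_sheet,
    select_mirnas,
)

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results"

CONTRAST = ("M1", "M0")
R_THRESHOLD = 0.5
P_THRESHOLD = 1e-4


def main() -> None:
    mrna = read_expression_matrix(SIM / "mrna_matrix.tsv", "mRNA")
    mirna = read_expression_matrix(SIM / "mirna_matrix.tsv", "miRNA")
    sheet = read_sample_sheet(SIM / "samples.tsv")
    db_a = read_gmt(SIM / "targets_mirandalike.gmt", role="targets")
    db_b = read_gmt(SIM / "targets_targetscanlike.gmt", role="targets")
    de_genes = pd.read_csv(OUT / f"de_mrna_{CONTRAST[0]}_vs_{CONTRAST[1]}.tsv", sep="\t").set_index(
        "feature_id", drop=False
    )
    de_mirnas = pd.read_csv(OUT / f"de_mirna_{CONTRAST[0]}_vs_{CONTRAST[1]}.tsv", sep="\t").set_index(
        "feature_id", drop=False
    )

    shortlist = select_mirnas(de_mirnas, mirna, "miR-709-like", 0.5, 0.05)
    print(f"shortlisted miRNAs: {list(shortlist.up)} up, {list(shortlist.down)} down")

    overlap_rows = []
    for mirna_id in shortlist.all:
        corr = correlate_mirna_genes(mirna, mrna, sheet, mirna_id, CONTRAST)
        candidates = filter_candidates(corr, de_genes, R_THRESHOLD, P_THRESHOLD)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            triple = intersect_targets(candidates, db_a, db_b, mirna_id)
        table = build_interactome(mirna_id, triple, corr, de_genes)
        n_pos, n_neg = classify_directions(table)
        stats = overlap_fractions(
            candidates, db_a.targets_for(mirna_id), db_b.targets_for(mirna_id)
        )
        table.to_csv(OUT / f"interactome_{mirna_id}.tsv", sep="\t", index=False)
        overlap_rows.append(
            {
                "mirna_id": mirna_id,
                "n_correlated_de": stats.n_correlated_de,
                "frac_overlap_a": stats.frac_overlap_a,
                "frac_overlap_b": stats.frac_overlap_b,
                "frac_triple": stats.frac_triple,
                "n_triple": stats.n_triple,
                "n_positive": n_pos,
                "n_negative": n_neg,
            }
        )
        print(f"{mirna_id}: {len(candidates)} correlated+DE genes -> "
              f"{stats.n_overlap_a} in {db_a.source_name}, {stats.n_overlap_b} in "
              f"{db_b.source_name} -> {len(triple)} triple "
              f"({n_pos} positively, {n_neg} inversely correlated)")

    pd.DataFrame(overlap_rows).to_csv(OUT / "overlap_stats.tsv", sep="\t", index=False)
    print(f"overlap statistics written to {OUT / 'overlap_stats.tsv'}")


if __name__ == "__main__":
    main()
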