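"""End-to-end orchestration: DE -> miRNA shortlist -> correlation screen ->
database intersection -> enrichment -> machine-readable summary.

Every stage is a pure function of its inputs and the configured thresholds,
so re-running a stage from saved intermediates reproduces the end-to-end
result.  The log records each threshold and the count surviving each filter,
mirroring the funnel the analysis narrates (correlated-and-DE genes ->
per-database overlap -> triple intersection).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential as de_mod
from . import enrichment as enr_mod
from . import targets as tg_mod
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleSheet,
    TargetDatabase,
    read_expression_matrix,
    read_gmt,
    read_sample_sheet,
)

__all__ = ["Thresholds", "PipelineConfig", "run_analysis", "run_pipeline"]

log = logging.getLogger("mirglia.pipeline")


@dataclass(frozen=True)
class Thresholds:
    """Filter settings; defaults follow the study's printed conventions."""

    mrna_p: float = 1e-4
    mirna_p: float = 0.05
    r: float = 0.5
    heatmap_q: float = 1e-7
    alpha: float = 0.05
    ref_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("mrna_p", "mirna_p", "r", "heatmap_q", "alpha", "ref_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"threshold {name} must be in (0, 1), got {v}")


@dataclass
class PipelineConfig:
    mrna_matrix: str
    mirna_matrix: str
    sample_sheet: str
    db_a: str
    db_b: str
    annotations: str
    outdir: str
    contrasts: list[tuple[str, str]] = field(default_factory=lambda: [("M1", "M0"), ("M2a", "M0")])
    reference_mirna: str = "miR-709"
    thresholds: Thresholds = field(default_factory=Thresholds)
    welch: bool = False
    correlation_all_samples: bool = False
    top_n: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.contrasts = [tuple(c) for c in self.contrasts]
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        self.thresholds.validate()
        for treated, control in self.contrasts:
            if treated == control:
                raise ValueError(f"contrast with treated == control: {treated!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_analysis(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    sheet: SampleSheet,
    db_a: TargetDatabase,
    db_b: TargetDatabase,
    annotations: GeneSetCollection,
    contrasts: list[tuple[str, str]],
    thresholds: Thresholds | None = None,
    reference_mirna: str = "miR-709",
    welch: bool = False,
    correlation_all_samples: bool = False,
    top_n: int = 15,
) -> dict:
    """The full analysis on in-memory inputs; returns all stage outputs.

    The result maps each ``"treated_vs_control"`` contrast name to its DE
    tables, Table-1-style summaries, miRNA shortlist, per-miRNA screens
    (correlations, candidate sets, interactomes, overlap stats, enrichment)
    and the pooled enrichment ranking, plus a JSON-ready ``summary``.
    """
    th = thresholds or Thresholds()
    th.validate()
    for cond_set, matrix in (("mRNA", mrna), ("miRNA", mirna)):
        sheet.validate_against(matrix)
    universe = frozenset(mrna.feature_ids)

    results: dict = {"contrasts": {}, "summary": {"contrasts": {}, "thresholds": dataclasses.asdict(th)}}
    for treated, control in contrasts:
        cname = f"{treated}_vs_{control}"
        log.info("contrast %s: differential expression", cname)
        de_genes = de_mod.run_contrast(mrna, sheet, treated, control, equal_var=not welch)
        de_mirnas = de_mod.run_contrast(mirna, sheet, treated, control, equal_var=not welch)
        gene_summary = de_mod.summarize_contrast(de_genes, th.mrna_p)
        mirna_summary = de_mod.summarize_contrast(de_mirnas, th.mirna_p)
        log.info(
            "contrast %s: %d/%d genes DE at p<%g (%d up / %d down)",
            cname, gene_summary.n_significant, gene_summary.n_tested,
            th.mrna_p, gene_summary.n_up, gene_summary.n_down,
        )
        shortlist = de_mod.select_mirnas(
            de_mirnas, mirna, reference_mirna, min_fraction=th.ref_fraction, p_threshold=th.mirna_p
        )
        log.info("contrast %s: shortlisted %d miRNAs (%d up, %d down)",
                 cname, len(shortlist.all), len(shortlist.up), len(shortlist.down))

        per_mirna: dict[str, dict] = {}
        enrichment_tables: list[pd.DataFrame] = []
        for mirna_id in shortlist.all:
            corr = tg_mod.correlate_mirna_genes(
                mirna, mrna, sheet, mirna_id,
                conditions=(treated, control), all_samples=correlation_all_samples,
            )
            candidates = tg_mod.filter_candidates(corr, de_genes, r_threshold=th.r, p_threshold=th.mrna_p)
            set_a = db_a.targets_for(mirna_id)
            set_b = db_b.targets_for(mirna_id)
            overlap = tg_mod.overlap_fractions(candidates, set_a, set_b)
            triple = tg_mod.intersect_targets(candidates, db_a, db_b, mirna_id)
            interactome = tg_mod.build_interactome(mirna_id, triple, corr, de_genes)
            n_pos, n_neg = tg_mod.classify_directions(interactome)
            log.info(
                "contrast %s, %s: %d correlated+DE -> %d in %s, %d in %s -> %d triple (%d pos / %d neg)",
                cname, mirna_id, len(candidates),
                overlap.n_overlap_a, db_a.source_name, overlap.n_overlap_b, db_b.source_name,
                len(triple), n_pos, n_neg,
            )
            enr = enr_mod.enrich(triple, annotations, universe, mirna_id=mirna_id) if triple else pd.DataFrame(
                columns=enr_mod.ENRICHMENT_COLUMNS
            )
            per_mirna[mirna_id] = {
                "correlations": corr,
                "candidates": candidates,
                "overlap": overlap,
                "interactome": interactome,
                "directions": (n_pos, n_neg),
                "enrichment": enr,
            }
            enrichment_tables.append(enr)

        pooled = enr_mod.pool_and_rank(enrichment_tables, alpha=th.alpha, top_n=top_n)
        results["contrasts"][cname] = {
            "de_genes": de_genes,
            "de_mirnas": de_mirnas,
            "gene_summary": gene_summary,
            "mirna_summary": mirna_summary,
            "shortlist": shortlist,
            "per_mirna": per_mirna,
            "pooled_enrichment": pooled,
        }
        results["summary"]["contrasts"][cname] = {
            "genes": dataclasses.asdict(gene_summary),
            "mirnas": dataclasses.asdict(mirna_summary),
            "shortlist_up": list(shortlist.up),
            "shortlist_down": list(shortlist.down),
            "interactomes": {
                m: {
                    "n_candidates": len(d["candidates"]),
                    "n_triple": len(d["interactome"]),
                    "n_positive": d["directions"][0],
                    "n_negative": d["directions"][1],
                    "frac_overlap_a": d["overlap"].frac_overlap_a,
                    "frac_overlap_b": d["overlap"].frac_overlap_b,
                    "frac_triple": d["overlap"].frac_triple,
                }
                for m, d in per_mirna.items()
            },
        }
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Load the configured inputs, run the analysis and write every artifact.

    Any stage failure aborts with the stage name and the offending input in
    the exception chain.  Returns the summary dict (also written as JSON).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        mrna = read_expression_matrix(config.mrna_matrix, "mRNA")
        mirna = read_expression_matrix(config.mirna_matrix, "miRNA")
        sheet = read_sample_sheet(config.sample_sheet)
        db_a = read_gmt(config.db_a, role="targets")
        db_b = read_gmt(config.db_b, role="targets")
        annotations = read_gmt(config.annotations, role="annotation")
    except Exception as exc:
        raise RuntimeError(f"stage 'load inputs' failed: {exc}") from exc

    results = run_analysis(
        mrna, mirna, sheet, db_a, db_b, annotations,
        contrasts=config.contrasts,
        thresholds=config.thresholds,
        reference_mirna=config.reference_mirna,
        welch=config.welch,
        correlation_all_samples=config.correlation_all_samples,
        top_n=config.top_n,
    )

    for cname, cres in results["contrasts"].items():
        cdir = outdir / cname
        cdir.mkdir(parents=True, exist_ok=True)
        cres["de_genes"].to_csv(cdir / "de_mrna.tsv", sep="\t", index=False)
        cres["de_mirnas"].to_csv(cdir / "de_mirna.tsv", sep="\t", index=False)
        for mirna_id, d in cres["per_mirna"].items():
            tag = mirna_id.replace("*", "star").replace("/", "_")
            d["interactome"].to_csv(cdir / f"interactome_{tag}.tsv", sep="\t", index=False)
            d["enrichment"].to_csv(cdir / f"enrichment_{tag}.tsv", sep="\t", index=False)
        cres["pooled_enrichment"].to_csv(cdir / "enrichment_pooled.tsv", sep="\t", index=False)

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(results["summary"], indent=2, sort_keys=True))
    log.info("summary written to %s", summary_path)
    return results["summary"]
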