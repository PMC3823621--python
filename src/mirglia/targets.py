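"""miRNA:mRNA candidate-target screening by correlation and set intersection.

The screen mirrors the published workflow: for a shortlisted miRNA, Pearson
correlation of its expression profile against every gene across the pooled
samples of the contrast's two conditions; genes must pass both a correlation
magnitude threshold (|r| > 0.5, strict) and a differential-expression
significance threshold (p < 1e-4, strict); the surviving genes are
intersected with two independent prediction databases; the triple
intersection is the candidate interactome, classified by correlation sign
into positively correlated and inversely (canonically repressed) targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    SampleSheet,
    TargetDatabase,
    normalize_gene_symbol,
    normalize_mirna_id,
)

__all__ = [
    "OverlapStats",
    "correlate_mirna_genes",
    "filter_candidates",
    "intersect_targets",
    "build_interactome",
    "classify_directions",
    "overlap_fractions",
    "load_published_interactome",
]

POSITIVE = "positively_correlated"
INVERSE = "inversely_correlated"

INTERACTOME_COLUMNS = [
    "mirna_id",
    "gene_symbol",
    "description",
    "correlation_factor",
    "log2_fold_change",
    "power",
    "direction",
]


def correlate_mirna_genes(
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    sheet: SampleSheet,
    mirna_id: str,
    conditions: tuple[str, str] | None = None,
    all_samples: bool = False,
) -> pd.DataFrame:
    """Pearson r between one miRNA and every gene.

    By default samples are restricted to the pooled replicates of the two
    contrast ``conditions`` (n = 6 in the study design); ``all_samples=True``
    correlates across every sample in the sheet instead.  Genes with zero
    variance across the used samples get r = 0 with ``degenerate=True``.
    """
    mid = normalize_mirna_id(mirna_id)
    if mid not in mirna_matrix.data.index:
        raise KeyError(f"miRNA {mid!r} absent from miRNA matrix")
    if all_samples or conditions is None:
        samples = sheet.sample_ids
    else:
        cond_a, cond_b = conditions
        samples = sheet.samples_for(cond_a) + sheet.samples_for(cond_b)
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples for correlation, got {len(samples)}")
    sheet.validate_against(mirna_matrix)
    sheet.validate_against(mrna_matrix)

    y = mirna_matrix.data.loc[mid, samples].to_numpy(dtype=float)
    G = mrna_matrix.data[samples].to_numpy(dtype=float)

    yc = y - y.mean()
    Gc = G - G.mean(axis=1, keepdims=True)
    y_ss = float(np.sum(yc * yc))
    g_ss = np.sum(Gc * Gc, axis=1)
    denom = np.sqrt(g_ss * y_ss)
    degenerate = (g_ss == 0) | (y_ss == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(degenerate, 0.0, Gc @ yc / np.where(denom == 0, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)

    out = pd.DataFrame(
        {
            "mirna_id": mid,
            "gene_id": mrna_matrix.feature_ids,
            "r": r,
            "n_samples": len(samples),
            "degenerate": degenerate,
        }
    )
    return out.set_index("gene_id", drop=False)


def filter_candidates(
    correlations: pd.DataFrame,
    de: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float = 1e-4,
) -> frozenset[str]:
    """Genes passing |r| > r_threshold AND DE p < p_threshold (both strict)."""
    common = correlations.index.intersection(de.index)
    r = correlations.loc[common, "r"]
    p = de.loc[common, "p_value"]
    keep = (r.abs() > r_threshold) & (p < p_threshold)
    return frozenset(common[keep])


def intersect_targets(
    candidates: frozenset[str] | set[str],
    db_a: TargetDatabase,
    db_b: TargetDatabase,
    mirna_id: str,
) -> frozenset[str]:
    """Triple intersection: candidates with both databases' predictions."""
    mid = normalize_mirna_id(mirna_id)
    sets = []
    for db in (db_a, db_b):
        if mid not in db:
            warnings.warn(
                f"miRNA {mid!r} absent from database {db.source_name!r}; "
                "contributing an empty prediction set",
                stacklevel=2,
            )
        sets.append(db.targets_for(mid))
    return frozenset(candidates) & sets[0] & sets[1]


def build_interactome(
    mirna_id: str,
    candidates: frozenset[str] | set[str],
    correlations: pd.DataFrame,
    de: pd.DataFrame,
    descriptions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per candidate gene, published-table shape.

    Rows are grouped positively-correlated first, then inversely correlated,
    each block sorted by descending |log2 fold change| with alphabetical
    tie-break on the gene symbol.
    """
    mid = normalize_mirna_id(mirna_id)
    descriptions = descriptions or {}
    rows = []
    for gene in candidates:
        if gene not in correlations.index:
            raise KeyError(f"candidate {gene!r} missing from correlation table")
        if gene not in de.index:
            raise KeyError(f"candidate {gene!r} missing from DE table")
        r = float(correlations.loc[gene, "r"])
        rows.append(
            {
                "mirna_id": mid,
                "gene_symbol": gene,
                "description": descriptions.get(gene, ""),
                "correlation_factor": r,
                "log2_fold_change": float(de.loc[gene, "log2_fold_change"]),
                "power": float(de.loc[gene, "p_value"]),
                "direction": INVERSE if r < 0 else POSITIVE,
            }
        )
    table = pd.DataFrame(rows, columns=INTERACTOME_COLUMNS)
    return sort_interactome(table)


def sort_interactome(table: pd.DataFrame) -> pd.DataFrame:
    """Canonical interactome ordering (positive block, then inverse block)."""
    if table.empty:
        return table.reset_index(drop=True)
    out = table.copy()
    out["_block"] = (out["direction"] == INVERSE).astype(int)
    out["_mag"] = -out["log2_fold_change"].abs()
    out = out.sort_values(["_block", "_mag", "gene_symbol"], kind="mergesort")
    return out.drop(columns=["_block", "_mag"]).reset_index(drop=True)


def classify_directions(interactome: pd.DataFrame) -> tuple[int, int]:
    """(n_positive, n_negative) partition of the interactome by direction."""
    if interactome.empty:
        return (0, 0)
    n_neg = int((interactome["direction"] == INVERSE).sum())
    return (len(interactome) - n_neg, n_neg)


@dataclass(frozen=True)
class OverlapStats:
    """Overlap of correlated-and-DE genes with each prediction source."""

    n_correlated_de: int
    n_db_a: int
    n_db_b: int
    n_overlap_a: int
    n_overlap_b: int
    n_triple: int
    frac_overlap_a: float
    frac_overlap_b: float
    frac_triple: float
    undefined: bool = False


def overlap_fractions(
    candidates: frozenset[str] | set[str],
    db_a_set: frozenset[str] | set[str],
    db_b_set: frozenset[str] | set[str],
) -> OverlapStats:
    """Pairwise and triple overlap fractions relative to the candidate set."""
    candidates = frozenset(candidates)
    a = frozenset(db_a_set)
    b = frozenset(db_b_set)
    n = len(candidates)
    inter_a = candidates & a
    inter_b = candidates & b
    triple = inter_a & inter_b
    if n == 0:
        return OverlapStats(0, len(a), len(b), 0, 0, 0, float("nan"), float("nan"), float("nan"), undefined=True)
    return OverlapStats(
        n_correlated_de=n,
        n_db_a=len(a),
        n_db_b=len(b),
        n_overlap_a=len(inter_a),
        n_overlap_b=len(inter_b),
        n_triple=len(triple),
        frac_overlap_a=len(inter_a) / n,
        frac_overlap_b=len(inter_b) / n,
        frac_triple=len(triple) / n,
    )


def load_published_interactome() -> pd.DataFrame:
    """The packaged reference interactome: 112 published miR-155 candidate
    targets in LPS-stimulated microglia.

    Values (correlation factor, log2 fold change, significance) are
    transcribed as printed; symbols are canonicalised and the direction
    column is derived from the correlation sign.
    """
    with resources.files("mirglia.data").joinpath("table2_mir155.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    table = pd.DataFrame(
        {
            "mirna_id": normalize_mirna_id("miR-155"),
            "gene_symbol": [normalize_gene_symbol(s) for s in raw["gene_symbol"]],
            "description": raw["description"].fillna(""),
            "correlation_factor": raw["correlation_factor"].astype(float),
            "log2_fold_change": raw["log2_fold_change"].astype(float),
            "power": raw["power"].astype(float),
        }
    )
    table["direction"] = np.where(table["correlation_factor"] < 0, INVERSE, POSITIVE)
    return table
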