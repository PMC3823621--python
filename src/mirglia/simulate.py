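"""Planted-truth synthetic paired miRNA/mRNA expression datasets.

Emulates the study design the pipeline was built for: three conditions
(resting M0, LPS-skewed M1, IL-4-skewed M2a) with three array replicates
each, log2-scale expression, a handful of strongly condition-responsive
marker features, and miRNA -> gene regulatory edges that couple gene
expression to miRNA expression (repressive edges give negative coupling,
the canonical miRNA mode; activating edges the positive one that is equally
common in observational correlation screens).

Effect-size presets mirror the headline magnitudes of the motivating study:
a 425-fold M1-induced gene (IL-6-like), a 38.85-fold M2a-induced gene
(CHI3L3-like), a 9.69-fold M1-induced miRNA (miR-155-like) and a 2.66-fold
M2a-induced miRNA (miR-145-like), plus a constitutively high reference
miRNA (miR-709-like) anchoring the expressed-miRNA shortlist rule.

The generative model, per feature f and sample s of condition c:

    mirna[f, s] = baseline_f + effect_{f,c} + eps,        eps ~ N(0, noise_sd)
    gene[g, s]  = baseline_g + effect_{g,c}
                  + sum_edges beta_e * (mirna[m_e, s] - baseline_{m_e}) + eps

so a gene downstream of an edge inherits both the miRNA's condition shift
(scaled by beta) and its per-sample noise, which is what makes the planted
edges recoverable by Pearson correlation at small n.

Prediction databases include each true edge independently with probability
``db_sensitivity`` and add ``db_noise`` random decoy predictions per miRNA;
the annotation collection holds one set per planted regulatory program plus
size-matched decoy sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleSheet,
    TargetDatabase,
    normalize_gene_symbol,
    write_expression_matrix,
    write_gmt,
    write_sample_sheet,
)

__all__ = [
    "PRESETS",
    "Preset",
    "SimConfig",
    "Edge",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "truth_report",
    "estimate_preset_recovery",
    "RecoveryReport",
]


@dataclass(frozen=True)
class Preset:
    feature: str  # generated feature id
    kind: str  # "gene" | "mirna"
    condition: str
    fold: float  # linear fold in that condition


PRESETS: dict[str, Preset] = {
    "il6_like": Preset("IL6LIKE", "gene", "M1", 425.0),
    "chi3l3_like": Preset("CHI3L3LIKE", "gene", "M2a", 38.85),
    "mir155_like": Preset("miR-155-like", "mirna", "M1", 9.69),
    "mir145_like": Preset("miR-145-like", "mirna", "M2a", 2.66),
}

REFERENCE_MIRNA = "miR-709-like"


@dataclass(frozen=True)
class Edge:
    mirna: str
    gene: str
    beta: float  # regression slope on log2 scale

    @property
    def sign(self) -> str:
        return "repressive" if self.beta < 0 else "activating"


@dataclass
class SimConfig:
    """Generator settings; the defaults emulate the study design."""

    n_genes: int = 200
    n_mirnas: int = 30
    conditions: tuple[str, ...] = ("M0", "M1", "M2a")
    n_replicates: int = 3
    noise_sd: float = 0.2  # log2 units
    presets: tuple[str, ...] = ("il6_like", "chi3l3_like", "mir155_like", "mir145_like")
    # regulatory programs: targets per program miRNA, split by edge sign
    n_repressive: int = 8
    n_activating: int = 5
    beta_repressive: float = -0.9
    beta_activating: float = 0.7
    # prediction databases
    db_sensitivity: float = 0.9
    db_noise: int = 5
    n_decoy_sets: int = 5
    # modest secondary miRNA responses (fold, condition) for realism
    n_modest_mirnas: int = 2
    modest_fold: float = 1.8

    def validate(self) -> None:
        if self.n_genes < 50:
            raise ValueError("need at least 50 genes")
        if self.n_mirnas < 10:
            raise ValueError("need at least 10 miRNAs")
        if len(self.conditions) < 2 or self.n_replicates < 3:
            raise ValueError("design needs >=2 conditions x >=3 replicates")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.db_sensitivity <= 1:
            raise ValueError("db_sensitivity must be in [0, 1]")
        for name in self.presets:
            if name not in PRESETS:
                raise ValueError(f"unknown preset {name!r}")
            if PRESETS[name].condition not in self.conditions:
                raise ValueError(f"preset {name!r} targets an absent condition")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery scoring."""

    dataset_id: str
    planted_mirna_effects: dict[str, tuple[str, float]]  # miRNA -> (condition, fold)
    planted_gene_effects: dict[str, tuple[str, float]]
    regulatory_edges: list[Edge]
    db_sensitivity: float
    db_noise: int
    noise_sd: float
    program_targets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def edges_for(self, mirna: str) -> list[Edge]:
        return [e for e in self.regulatory_edges if e.mirna == mirna]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["regulatory_edges"] = [
            {"mirna": e.mirna, "gene": e.gene, "beta": e.beta, "sign": e.sign}
            for e in self.regulatory_edges
        ]
        return json.dumps(payload, indent=2)


@dataclass
class SyntheticDataset:
    dataset_id: str
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    sheet: SampleSheet
    db_a: TargetDatabase
    db_b: TargetDatabase
    annotations: GeneSetCollection
    truth: SyntheticTruth


def generate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate one paired dataset; bit-identical for identical (config, seed)."""
    config = config or SimConfig()
    config.validate()
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    dataset_id = f"mirglia-sim-{seed}"

    samples = [f"{c}_{r}" for c in config.conditions for r in range(1, config.n_replicates + 1)]
    sample_cond = [c for c in config.conditions for _ in range(config.n_replicates)]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "condition": sample_cond,
                "replicate": [r for _ in config.conditions for r in range(1, config.n_replicates + 1)],
            }
        )
    )

    # --- feature names -----------------------------------------------------
    preset_genes = [PRESETS[p].feature for p in config.presets if PRESETS[p].kind == "gene"]
    preset_mirnas = [PRESETS[p].feature for p in config.presets if PRESETS[p].kind == "mirna"]
    n_generic_genes = config.n_genes - len(preset_genes)
    n_generic_mirnas = config.n_mirnas - len(preset_mirnas) - 1  # reference miRNA
    if n_generic_genes < 30 or n_generic_mirnas < 4:
        raise ValueError("counts too small for the planted structure")
    genes = preset_genes + [f"GENE{i:04d}" for i in range(n_generic_genes)]
    mirnas = preset_mirnas + [REFERENCE_MIRNA] + [f"miR-9{i:03d}-sim" for i in range(n_generic_mirnas)]

    # --- baselines ---------------------------------------------------------
    gene_base = rng.uniform(4.0, 10.0, size=len(genes))
    mirna_base = rng.uniform(3.0, 8.0, size=len(mirnas))
    mirna_base[mirnas.index(REFERENCE_MIRNA)] = 11.0  # highest-expressing miRNA
    # program miRNAs are well expressed, clearing the 50%-of-reference rule
    for m in preset_mirnas:
        mirna_base[mirnas.index(m)] = rng.uniform(10.0, 10.8)

    # --- condition effects -------------------------------------------------
    cond_of_sample = np.array(sample_cond)
    mirna_effect = np.zeros((len(mirnas), len(samples)))
    gene_effect = np.zeros((len(genes), len(samples)))
    planted_mirna_effects: dict[str, tuple[str, float]] = {}
    planted_gene_effects: dict[str, tuple[str, float]] = {}

    for name in config.presets:
        p = PRESETS[name]
        mask = cond_of_sample == p.condition
        shift = np.log2(p.fold)
        if p.kind == "gene":
            gene_effect[genes.index(p.feature), mask] += shift
            planted_gene_effects[p.feature] = (p.condition, p.fold)
        else:
            mirna_effect[mirnas.index(p.feature), mask] += shift
            planted_mirna_effects[p.feature] = (p.condition, p.fold)

    # modest secondary miRNA responses, alternating up/down across conditions
    generic_mirna_ids = [m for m in mirnas if m not in preset_mirnas and m != REFERENCE_MIRNA]
    responsive_conditions = [c for c in config.conditions[1:]] or [config.conditions[0]]
    for i in range(min(config.n_modest_mirnas, len(generic_mirna_ids))):
        m = generic_mirna_ids[i]
        cond = responsive_conditions[i % len(responsive_conditions)]
        fold = config.modest_fold if i % 2 == 0 else 1.0 / config.modest_fold
        mirna_effect[mirnas.index(m), cond_of_sample == cond] += np.log2(fold)
        planted_mirna_effects[m] = (cond, fold)

    # --- regulatory edges --------------------------------------------------
    program_mirnas = preset_mirnas
    n_targets = config.n_repressive + config.n_activating
    assignable = [g for g in genes if g not in preset_genes]
    if n_targets * len(program_mirnas) > len(assignable):
        raise ValueError("not enough genes for the requested regulatory programs")
    picked = rng.choice(len(assignable), size=n_targets * len(program_mirnas), replace=False)
    edges: list[Edge] = []
    program_targets: dict[str, tuple[str, ...]] = {}
    for j, m in enumerate(program_mirnas):
        block = [assignable[i] for i in picked[j * n_targets : (j + 1) * n_targets]]
        betas = np.concatenate(
            [
                config.beta_repressive * rng.uniform(0.8, 1.2, size=config.n_repressive),
                config.beta_activating * rng.uniform(0.8, 1.2, size=config.n_activating),
            ]
        )
        for g, beta in zip(block, betas):
            edges.append(Edge(mirna=m, gene=g, beta=float(beta)))
        program_targets[m] = tuple(block)

    # --- expression grids --------------------------------------------------
    mirna_values = (
        mirna_base[:, None]
        + mirna_effect
        + rng.normal(0.0, config.noise_sd, size=(len(mirnas), len(samples)))
    )
    gene_values = (
        gene_base[:, None]
        + gene_effect
        + rng.normal(0.0, config.noise_sd, size=(len(genes), len(samples)))
    )
    for e in edges:
        gi = genes.index(e.gene)
        mi = mirnas.index(e.mirna)
        gene_values[gi] += e.beta * (mirna_values[mi] - mirna_base[mi])

    mrna = ExpressionMatrix(pd.DataFrame(gene_values, index=genes, columns=samples), "mRNA")
    mirna = ExpressionMatrix(pd.DataFrame(mirna_values, index=mirnas, columns=samples), "miRNA")

    # --- prediction databases ----------------------------------------------
    norm_genes = [normalize_gene_symbol(g) for g in genes]

    def _make_db(name: str) -> TargetDatabase:
        targets: dict[str, frozenset[str]] = {}
        for m in mirnas:
            true = [e.gene for e in edges if e.mirna == m]
            kept = [g for g in true if rng.random() < config.db_sensitivity]
            non_targets = [g for g in norm_genes if g not in set(normalize_gene_symbol(t) for t in true)]
            n_decoy = min(config.db_noise, len(non_targets))
            decoys = list(rng.choice(non_targets, size=n_decoy, replace=False)) if n_decoy else []
            members = set(normalize_gene_symbol(g) for g in kept) | set(decoys)
            if members:
                targets[m] = frozenset(members)
        return TargetDatabase(source_name=name, targets=targets)

    db_a = _make_db("mirandalike")
    db_b = _make_db("targetscanlike")

    # --- annotation collection ----------------------------------------------
    sets: dict[str, frozenset[str]] = {}
    for m, block in program_targets.items():
        set_name = f"{m.upper().replace('-', '_')}_PROGRAM"
        sets[set_name] = frozenset(normalize_gene_symbol(g) for g in block)
    decoy_size = n_targets
    for i in range(config.n_decoy_sets):
        members = rng.choice(norm_genes, size=decoy_size, replace=False)
        sets[f"DECOY_SET_{i:02d}"] = frozenset(members)
    annotations = GeneSetCollection(collection_name="synthetic_networks", sets=sets)

    truth = SyntheticTruth(
        dataset_id=dataset_id,
        planted_mirna_effects=planted_mirna_effects,
        planted_gene_effects=planted_gene_effects,
        regulatory_edges=edges,
        db_sensitivity=config.db_sensitivity,
        db_noise=config.db_noise,
        noise_sd=config.noise_sd,
        program_targets=program_targets,
    )
    return SyntheticDataset(
        dataset_id=dataset_id,
        mrna=mrna,
        mirna=mirna,
        sheet=sheet,
        db_a=db_a,
        db_b=db_b,
        annotations=annotations,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every component in its standard text format; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": outdir / "mrna_matrix.tsv",
        "mirna": outdir / "mirna_matrix.tsv",
        "sheet": outdir / "samples.tsv",
        "db_a": outdir / "targets_mirandalike.gmt",
        "db_b": outdir / "targets_targetscanlike.gmt",
        "annotations": outdir / "networks.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression_matrix(dataset.mrna, paths["mrna"])
    write_expression_matrix(dataset.mirna, paths["mirna"])
    write_sample_sheet(dataset.sheet, paths["sheet"])
    write_gmt(dataset.db_a, paths["db_a"])
    write_gmt(dataset.db_b, paths["db_b"])
    write_gmt(dataset.annotations, paths["annotations"])
    paths["truth"].write_text(dataset.truth.to_json())
    return paths


def estimate_preset_recovery(
    config: SimConfig | None = None,
    n_seeds: int = 200,
    base_seed: int = 1,
) -> dict[str, float]:
    """Mean recovered linear fold per preset over seeded replicate datasets.

    For each seed a fresh dataset is generated and the planted feature's
    linear fold is estimated by the differential-expression stage (preset
    condition vs the resting condition); returns the per-preset mean.
    """
    from .differential import run_contrast

    config = config or SimConfig()
    control = config.conditions[0]
    sums = {name: 0.0 for name in config.presets}
    for i in range(n_seeds):
        d = generate_dataset(config, seed=base_seed + i)
        de_cache: dict[tuple[str, str], pd.DataFrame] = {}
        for name in config.presets:
            p = PRESETS[name]
            key = (p.kind, p.condition)
            if key not in de_cache:
                matrix = d.mrna if p.kind == "gene" else d.mirna
                de_cache[key] = run_contrast(matrix, d.sheet, p.condition, control)
            sums[name] += float(de_cache[key].loc[p.feature, "linear_fold"])
    return {name: total / n_seeds for name, total in sums.items()}


@dataclass(frozen=True)
class RecoveryReport:
    """How well pipeline output recovered the planted structure."""

    dataset_id: str
    mirna_id: str
    n_true_targets: int
    n_predicted: int
    n_recovered: int
    precision: float
    recall: float
    fold_estimates: dict[str, tuple[float, float]]  # feature -> (planted, estimated)


def truth_report(
    truth: SyntheticTruth,
    dataset_id: str,
    mirna_id: str,
    interactome: pd.DataFrame,
    de_genes: pd.DataFrame,
    contrast_condition: str | None = None,
) -> RecoveryReport:
    """Score an interactome (and DE folds) against the planted truth.

    ``dataset_id`` must match the truth's embedded id — passing output from
    a different generated dataset is an error, not a silent zero score.
    """
    if dataset_id != truth.dataset_id:
        raise ValueError(
            f"dataset/truth mismatch: output from {dataset_id!r}, truth from {truth.dataset_id!r}"
        )
    true_targets = {normalize_gene_symbol(e.gene) for e in truth.edges_for(mirna_id)}
    predicted = set(interactome["gene_symbol"]) if len(interactome) else set()
    recovered = true_targets & predicted
    precision = len(recovered) / len(predicted) if predicted else float("nan")
    recall = len(recovered) / len(true_targets) if true_targets else float("nan")

    fold_estimates: dict[str, tuple[float, float]] = {}
    for gene, (cond, fold) in truth.planted_gene_effects.items():
        if contrast_condition is not None and cond != contrast_condition:
            continue
        g = normalize_gene_symbol(gene)
        if g in de_genes.index:
            fold_estimates[g] = (fold, float(de_genes.loc[g, "linear_fold"]))

    return RecoveryReport(
        dataset_id=dataset_id,
        mirna_id=mirna_id,
        n_true_targets=len(true_targets),
        n_predicted=len(predicted),
        n_recovered=len(recovered),
        precision=precision,
        recall=recall,
        fold_estimates=fold_estimates,
    )
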