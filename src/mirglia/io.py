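"""Readers, writers and containers for the tabular inputs of the pipeline.

All expression values are exchanged on log2 scale.  Gene symbols are
canonicalised to upper case so that set operations across the expression
matrix, prediction databases and annotation collections are well defined;
miRNA identifiers keep the field's ``miR-``/``let-`` casing convention and
their star suffix, with species prefixes (``mmu-`` etc.) stripped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "TargetDatabase",
    "GeneSetCollection",
    "normalize_gene_symbol",
    "normalize_mirna_id",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
]

_SPECIES_PREFIX = re.compile(r"^[A-Za-z]{3,4}-(?=let-|mir|miR|MIR|MiR)")
_MIR_STEM = re.compile(r"^mir(?=[-\d])", re.IGNORECASE)


def normalize_gene_symbol(raw: str) -> str:
    """Canonical gene symbol: stripped and upper-cased.

    Raises ``ValueError`` on empty / whitespace-only input.
    """
    s = str(raw).strip()
    if not s:
        raise ValueError("empty gene symbol")
    return s.upper()


def normalize_mirna_id(raw: str) -> str:
    """Canonical miRNA id.

    Strips surrounding whitespace and a species prefix (``mmu-``, ``hsa-``),
    and normalises the stem casing to ``miR-`` (``let-`` ids are left as
    printed).  Star suffixes (``miR-191*``) are preserved: star forms are
    distinct array features from their mates.  Idempotent.
    """
    s = str(raw).strip()
    if not s:
        raise ValueError("empty miRNA id")
    while True:  # prefixes can stack in sloppy inputs ("mmu-mmu-miR-1")
        stripped = _SPECIES_PREFIX.sub("", s)
        if stripped == s:
            break
        s = stripped
    m = _MIR_STEM.match(s)
    if m:
        s = "miR" + s[m.end():]
    return s


def _normalizer_for(feature_kind: str):
    if feature_kind == "miRNA":
        return normalize_mirna_id
    return normalize_gene_symbol


@dataclass
class ExpressionMatrix:
    """Log2 expression, features (rows) by samples (columns).

    ``data`` holds the grid; the index carries normalized feature ids and
    columns the sample ids.  ``feature_kind`` is ``"mRNA"`` or ``"miRNA"``
    and selects the symbol normalizer applied at construction.
    """

    data: pd.DataFrame
    feature_kind: str = "mRNA"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("mRNA", "miRNA"):
            raise ValueError(f"feature_kind must be mRNA or miRNA, got {self.feature_kind!r}")
        norm = _normalizer_for(self.feature_kind)
        mapped = [norm(f) for f in self.data.index]
        seen: dict[str, str] = {}
        for orig, new in zip(self.data.index, mapped):
            if new in seen and seen[new] != str(orig):
                raise ValueError(
                    f"duplicate feature id after normalization: {seen[new]!r} and "
                    f"{orig!r} both map to {new!r}"
                )
            seen.setdefault(new, str(orig))
        if len(set(mapped)) != len(mapped):
            dupes = pd.Index(mapped)[pd.Index(mapped).duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        df = self.data.copy()
        df.index = pd.Index(mapped, name="feature_id")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data[samples], self.feature_kind)


@dataclass
class SampleSheet:
    """Sample-to-condition assignment with replicate numbers."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "replicate")

    def __post_init__(self) -> None:
        df = self.data
        unknown = [c for c in df.columns if c not in self.REQUIRED]
        if unknown:
            raise ValueError(f"unknown sample-sheet column(s): {unknown}")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing sample-sheet column(s): {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        reps = pd.to_numeric(df["replicate"], errors="raise")
        if (reps <= 0).any() or (reps != reps.astype(int)).any():
            raise ValueError("replicate must be a positive integer")
        out = df.copy()
        out["sample_id"] = out["sample_id"].astype(str)
        out["condition"] = out["condition"].astype(str)
        out["replicate"] = reps.astype(int)
        self.data = out.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.data.loc[self.data["condition"] == condition, "sample_id"]
        return list(sel)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Cross-check that every sheet sample exists in the matrix."""
        missing = [s for s in self.sample_ids if s not in matrix.data.columns]
        if missing:
            raise ValueError(f"sample sheet references samples absent from matrix: {missing}")


@dataclass
class TargetDatabase:
    """Predicted miRNA -> target-gene sets from one source (e.g. miRanda-like)."""

    source_name: str
    targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = {
            normalize_mirna_id(m): frozenset(normalize_gene_symbol(g) for g in genes)
            for m, genes in self.targets.items()
        }

    def targets_for(self, mirna_id: str) -> frozenset[str]:
        """Predicted targets; the empty set for a miRNA absent from this source."""
        return self.targets.get(normalize_mirna_id(mirna_id), frozenset())

    def __contains__(self, mirna_id: str) -> bool:
        return normalize_mirna_id(mirna_id) in self.targets


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets used as the annotation space for enrichment."""

    collection_name: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {
            str(name): frozenset(normalize_gene_symbol(g) for g in genes)
            for name, genes in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Tabular readers / writers


def read_expression_matrix(path: str | Path, feature_kind: str = "mRNA") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature id, one header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {df.index[i]!r}, sample {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at feature {df.index[i]!r}, sample {df.columns[j]!r}")
    return ExpressionMatrix(numeric, feature_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, role: str = "annotation"):
    """Read a GMT file.

    ``role="targets"`` returns a :class:`TargetDatabase` keyed by miRNA id;
    ``role="annotation"`` returns a :class:`GeneSetCollection`.  Each line
    must have name, description and at least one member.
    """
    if role not in ("targets", "annotation"):
        raise ValueError(f"role must be 'targets' or 'annotation', got {role!r}")
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, _desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"{path.name}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
    if role == "targets":
        return TargetDatabase(source_name=path.stem, targets={k: frozenset(v) for k, v in sets.items()})
    return GeneSetCollection(collection_name=path.stem, sets={k: frozenset(v) for k, v in sets.items()})


def write_gmt(obj: TargetDatabase | GeneSetCollection, path: str | Path) -> None:
    if isinstance(obj, TargetDatabase):
        name, mapping = obj.source_name, obj.targets
    else:
        name, mapping = obj.collection_name, obj.sets
    with open(path, "w") as fh:
        for set_name in sorted(mapping):
            members = sorted(mapping[set_name])
            if not members:
                continue  # GMT cannot represent an empty set
            fh.write("\t".join([set_name, name, *members]) + "\n")
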