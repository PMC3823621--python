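"""Two-group differential expression on log2 matrices.

The study design is three conditions (resting M0, LPS-driven M1, IL-4-driven
M2a) with three array replicates each; every contrast is treated-vs-control
on log2 expression with a two-sided Student's t-test (pooled variance by
default, Welch available as an option) and Benjamini-Hochberg adjustment
across all tested features.  Also provides the threshold-based contrast
summary (Table-1-style up/down counts), the expressed-miRNA shortlist rule
(mean expression above a fraction of the highest-expressing reference
miRNA), and the RT-PCR validation arithmetic (delta-delta-CT folds and
cross-method Pearson r-squared).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleSheet, normalize_mirna_id

__all__ = [
    "ContrastSummary",
    "MirnaShortlist",
    "run_contrast",
    "bh_adjust",
    "summarize_contrast",
    "select_mirnas",
    "fold_from_ddct",
    "ddct_from_fold",
    "method_concordance",
]

DE_COLUMNS = [
    "feature_id",
    "mean_treated",
    "mean_control",
    "log2_fold_change",
    "linear_fold",
    "t",
    "p_value",
    "q_value",
    "degenerate",
]


def linear_fold_from_log2(log2_fc: np.ndarray | float):
    """Signed linear fold: |fold| = 2^|log2FC|, sign follows the log2FC.

    A log2 fold change of 0 maps to fold 1 (no change).
    """
    arr = np.asarray(log2_fc, dtype=float)
    fold = np.where(arr >= 0, np.exp2(np.abs(arr)), -np.exp2(np.abs(arr)))
    fold = np.where(arr == 0, 1.0, fold)
    if np.isscalar(log2_fc) or arr.ndim == 0:
        return float(fold)
    return fold


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if not np.isfinite(arr).all() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def run_contrast(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    treated: str,
    control: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature differential expression for one two-group contrast.

    Returns a DataFrame with one row per feature: group means, log2 fold
    change (treated minus control), signed linear fold, t statistic, two-sided
    p, BH q over all tested features, and a ``degenerate`` flag for features
    with zero variance in both groups (t is set to 0 and p to 1 when the
    group means also coincide).
    """
    if treated == control:
        raise ValueError("treated and control conditions must differ")
    for cond in (treated, control):
        if cond not in sheet.conditions:
            raise ValueError(f"condition {cond!r} absent from sample sheet")
    sheet.validate_against(matrix)
    t_samples = sheet.samples_for(treated)
    c_samples = sheet.samples_for(control)
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("each contrast group needs at least 2 replicates")

    a = matrix.data[t_samples].to_numpy()
    b = matrix.data[c_samples].to_numpy()
    mean_t = a.mean(axis=1)
    mean_c = b.mean(axis=1)
    log2_fc = mean_t - mean_c

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant features trip scipy's catastrophic-cancellation warning;
        # their t/p are overwritten below
        warnings.filterwarnings("ignore", message="Precision loss occurred", category=RuntimeWarning)
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)

    var_t = a.var(axis=1, ddof=1)
    var_c = b.var(axis=1, ddof=1)
    degenerate = (var_t == 0) & (var_c == 0)
    flat = degenerate & (log2_fc == 0)
    separated = degenerate & (log2_fc != 0)
    t_stat[flat] = 0.0
    p[flat] = 1.0
    t_stat[separated] = np.sign(log2_fc[separated]) * np.inf
    p[separated] = 0.0
    if np.isnan(p).any():
        # zero pooled variance with unequal means already handled above
        raise RuntimeError("t-test produced NaN p-values")

    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "mean_treated": mean_t,
            "mean_control": mean_c,
            "log2_fold_change": log2_fc,
            "linear_fold": linear_fold_from_log2(log2_fc),
            "t": t_stat,
            "p_value": p,
            "q_value": bh_adjust(p),
            "degenerate": degenerate,
        }
    )
    return out.set_index("feature_id", drop=False)


@dataclass(frozen=True)
class ContrastSummary:
    n_tested: int
    n_significant: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float


def summarize_contrast(records: pd.DataFrame, p_threshold: float) -> ContrastSummary:
    """Up/down counts at a p threshold, Table-1 style.

    Significant features with a log2 fold change of exactly zero belong to
    neither class (they cannot arise from a finite t statistic, only from
    degenerate inputs).
    """
    sig = records[records["p_value"] < p_threshold]
    n_sig = len(sig)
    n_up = int((sig["log2_fold_change"] > 0).sum())
    n_down = int((sig["log2_fold_change"] < 0).sum())
    denom = n_up + n_down
    pct_up = 100.0 * n_up / denom if denom else 0.0
    pct_down = 100.0 * n_down / denom if denom else 0.0
    return ContrastSummary(
        n_tested=len(records),
        n_significant=n_sig,
        n_up=n_up,
        n_down=n_down,
        pct_up=pct_up,
        pct_down=pct_down,
    )


@dataclass(frozen=True)
class MirnaShortlist:
    up: tuple[str, ...]
    down: tuple[str, ...]

    @property
    def all(self) -> tuple[str, ...]:
        return self.up + self.down


def select_mirnas(
    mirna_records: pd.DataFrame,
    matrix: ExpressionMatrix,
    reference_mirna: str,
    min_fraction: float = 0.5,
    p_threshold: float = 0.05,
) -> MirnaShortlist:
    """Shortlist differentially expressed miRNAs that are well expressed.

    Keeps miRNAs with p below the threshold whose mean expression, on linear
    scale (2 to the mean log2 across all samples), exceeds ``min_fraction``
    of the reference miRNA's mean — strictly, so a miRNA at exactly the
    fraction is excluded.  The reference is the highest-expressing miRNA on
    the platform (miR-709 in microglia).
    """
    ref = normalize_mirna_id(reference_mirna)
    if ref not in matrix.data.index:
        raise KeyError(f"reference miRNA {ref!r} absent from matrix")
    mean_log2 = matrix.data.mean(axis=1)
    mean_linear = np.exp2(mean_log2)
    cutoff = min_fraction * mean_linear.loc[ref]

    up: list[str] = []
    down: list[str] = []
    for fid, row in mirna_records.iterrows():
        if row["p_value"] >= p_threshold:
            continue
        if fid not in mean_linear.index or not mean_linear.loc[fid] > cutoff:
            continue
        if row["log2_fold_change"] > 0:
            up.append(str(fid))
        elif row["log2_fold_change"] < 0:
            down.append(str(fid))
    return MirnaShortlist(up=tuple(up), down=tuple(down))


def fold_from_ddct(ddct) -> float | np.ndarray:
    """Relative expression fold from a delta-delta-CT value: fold = 2^(-ddCT)."""
    out = np.exp2(-np.asarray(ddct, dtype=float))
    return float(out) if np.ndim(ddct) == 0 else out


def ddct_from_fold(fold) -> float | np.ndarray:
    """Inverse of :func:`fold_from_ddct`; requires a positive fold."""
    arr = np.asarray(fold, dtype=float)
    if (arr <= 0).any():
        raise ValueError("fold must be positive")
    out = -np.log2(arr)
    return float(out) if np.ndim(fold) == 0 else out


def method_concordance(values_a, values_b) -> float:
    """Cross-method agreement as squared Pearson correlation of paired values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)
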