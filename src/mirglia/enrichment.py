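"""Hypergeometric over-representation of interactome genes in annotation sets.

The published workflow scored candidate-target sets against a proprietary
curated network knowledge base; here the scoring is a transparent one-sided
hypergeometric test of each user-supplied annotation set against the query,
with the measured genes (the expression matrix's symbols) as the sampling
universe, BH adjustment across the collection, and ranking by -log10(p) with
the conventional p < 0.05 line at 1.30.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "hypergeometric_p",
    "enrich",
    "pool_and_rank",
    "significance_line",
]

ENRICHMENT_COLUMNS = [
    "mirna_id",
    "set_name",
    "k_overlap",
    "set_size",
    "query_size",
    "universe_size",
    "p_value",
    "q_value",
    "neg_log10_p",
]


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Right tail P(X >= k): >=k annotated genes in a query of n from a
    universe of N containing K annotated genes."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K, n <= N; got K={K}, n={n}, N={N}")
    if k < 0 or k > K or k > n:
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: frozenset[str] | set[str],
    collection: GeneSetCollection,
    universe: frozenset[str] | set[str],
    mirna_id: str = "",
) -> pd.DataFrame:
    """Test every annotation set for over-representation in the query.

    Query genes outside the universe are dropped with a warning; each
    annotation set is intersected with the universe before testing.  Returns
    one row per set with BH q across the collection.  An empty (effective)
    query yields an empty table, flagged by warning.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped", stacklevel=2
        )
        query &= universe
    if not query:
        warnings.warn("empty query; no enrichment computed", stacklevel=2)
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    N = len(universe)
    n = len(query)
    rows = []
    for set_name in sorted(collection.sets):
        members = collection.sets[set_name] & universe
        K = len(members)
        k = len(query & members)
        p = hypergeometric_p(k, K, n, N)
        rows.append(
            {
                "mirna_id": mirna_id,
                "set_name": set_name,
                "k_overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["neg_log10_p"] = -np.log10(table["p_value"])
    return table[ENRICHMENT_COLUMNS]


def significance_line(alpha: float = 0.05) -> float:
    """The -log10(alpha) ranking threshold (1.30 at alpha = 0.05)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha))


def pool_and_rank(
    per_mirna: list[pd.DataFrame],
    alpha: float = 0.05,
    top_n: int = 15,
) -> pd.DataFrame:
    """Concatenate per-miRNA enrichment tables and rank by -log10(p).

    Duplicate set names from different miRNAs stay as separate rows (each
    bar in the published ranking carries its corresponding miRNA).  The
    returned table is annotated with the significance line and truncated to
    ``top_n`` rows.
    """
    frames = [t for t in per_mirna if not t.empty]
    if not frames:
        pooled = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    else:
        pooled = pd.concat(frames, ignore_index=True)
        pooled = pooled.sort_values(
            ["neg_log10_p", "set_name", "mirna_id"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    line = significance_line(alpha)
    out = pooled.head(top_n).copy()
    out["significant"] = out["neg_log10_p"] > line if len(out) else pd.Series(dtype=bool)
    out.attrs["significance_line"] = line
    return out
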