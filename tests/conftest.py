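import numpy as np
import pandas as pd
import pytest

from mirglia import ExpressionMatrix, SampleSheet, SimConfig, generate_dataset


@pytest.fixture
def sheet_3x3() -> SampleSheet:
    """The study design: 3 conditions x 3 replicates."""
    rows = [
        {"sample_id": f"{c}_{r}", "condition": c, "replicate": r}
        for c in ("M0", "M1", "M2a")
        for r in (1, 2, 3)
    ]
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def small_dataset():
    """A small noisy planted-truth dataset, fixed seed.

    noise_sd 0.1 keeps the planted program within reach of the strict
    p < 1e-4 gene filter at n = 3 (the edge-propagated miRNA noise roughly
    doubles a target gene's variance).
    """
    return generate_dataset(SimConfig(n_genes=80, n_mirnas=12, noise_sd=0.1), seed=11)


@pytest.fixture
def clean_dataset():
    """Zero-noise, perfectly sensitive databases: every stage is exact."""
    cfg = SimConfig(
        n_genes=80, n_mirnas=12, noise_sd=0.0, db_sensitivity=1.0, db_noise=0,
        n_modest_mirnas=0,
    )
    return generate_dataset(cfg, seed=5)


def make_matrix(values, features, samples, kind="mRNA") -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=features, columns=samples),
        kind,
    )
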