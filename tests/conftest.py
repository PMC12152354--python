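import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from placmed.io import CountMatrix
from placmed.simulate import CellTypeSpec, SimConfig, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_count_matrix(counts, sample_ids=None, cell_types=None, sides=None, gene_ids=None):
    """Small dense-array-backed CountMatrix for unit tests."""
    counts = np.asarray(counts)
    n_g, n_b = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_g)]
    barcodes = [f"bc{j}" for j in range(n_b)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids or ["s1"] * n_b,
            "cell_type": cell_types or ["T"] * n_b,
            "side": sides or ["maternal"] * n_b,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        gene_names=list(gene_ids),
        barcodes=barcodes,
        nucleus_meta=meta,
    )


SMALL_CFG = SimConfig(
    seed=7,
    n_samples=8,
    nuclei_per_sample=80,
    n_genes=400,
    n_genes_hypoxia=40,
    n_genes_nbi=40,
    n_subjects=60,
    cell_types=(
        CellTypeSpec("EVT", 0.35, 0.8, h0=0.4, m0=0.8),
        CellTypeSpec("SCT", 0.35, 0.4, h0=0.2, m0=0.2),
        CellTypeSpec("FB", 0.30, 0.1),
    ),
)


def shapiro_fixtures(seed, n_fixtures=50):
    """The deterministic vectors whose Shapiro-Wilk W values were frozen from
    R's shapiro.test; draw order must not change."""
    rng = np.random.default_rng(seed)
    for i in range(n_fixtures):
        n = int(rng.integers(10, 300))
        kind = i % 5
        if kind == 0:
            x = rng.normal(size=n)
        elif kind == 1:
            x = rng.exponential(size=n)
        elif kind == 2:
            x = rng.uniform(size=n)
        elif kind == 3:
            x = np.exp(rng.normal(size=n))
        else:
            x = rng.standard_t(3, size=n)
        yield x


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort shared across unit tests (8 samples x 80 nuclei x 400 genes)."""
    return generate_cohort(SMALL_CFG)
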