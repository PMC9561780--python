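import numpy as np
import pandas as pd
import pytest

from cscc_spatial import synthetic
from cscc_spatial.spatial import BinMatrix, BinSpec
from scipy import sparse


@pytest.fixture(scope="session")
def universe():
    """Small default universe shared across tests (340 genes)."""
    return synthetic.default_universe(n_genes=340, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_expr(rng):
    """50 units x 120 genes log-normal expression table."""
    genes = [f"g{i:03d}" for i in range(120)]
    vals = np.log1p(rng.lognormal(0, 1, size=(50, 120)))
    return pd.DataFrame(vals, index=[f"u{i}" for i in range(50)], columns=genes)


def make_binmat(counts: np.ndarray, coords=None) -> BinMatrix:
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    if coords is None:
        coords = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    genes = [f"g{j}" for j in range(counts.shape[1])]
    return BinMatrix(
        bin_coords=np.asarray(coords),
        genes=genes,
        counts=sparse.csr_matrix(counts),
        bin_spec=BinSpec(1),
    )
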