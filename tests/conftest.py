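import numpy as np
import pytest
import scipy.sparse as sp

from cryptshift import UmiMatrix
from cryptshift.dimred_cluster import Embedding


def make_umi(counts, mito_flags=None, sample=None, condition=None):
    """Build a UmiMatrix from a dense count array with default metadata."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    return UmiMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_ids=[f"g{j}" for j in range(n_genes)],
        mito_flags=(
            np.zeros(n_genes, bool) if mito_flags is None else mito_flags
        ),
        sample_label=["s0"] * n_cells if sample is None else sample,
        condition_label=["x"] * n_cells if condition is None else condition,
    )


def make_embedding(points):
    """Wrap raw coordinates as a trivial (identity-loading) embedding."""
    points = np.asarray(points, dtype=float)
    d = points.shape[1]
    return Embedding(
        scores=points,
        loadings=np.eye(d),
        explained_variance=np.ones(d),
        gene_ids=np.array([f"g{j}" for j in range(d)], dtype=object),
        centered=False,
        scaled=False,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
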