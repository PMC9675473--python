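import numpy as np
import pytest
import scipy.sparse as sp

from nephromac.core_io import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 3 cells with a mitochondrial gene in the middle row."""
    dense = np.array(
        [
            [3, 0, 1],  # A
            [0, 5, 0],  # mt-B
            [1, 0, 2],  # C
        ]
    )
    return ExpressionMatrix(
        sp.csr_matrix(dense), ["A", "mt-B", "C"], ["c1", "c2", "c3"], layer="raw"
    )


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    """50 genes x 40 cells of sparse Poisson counts, seeded."""
    rng = np.random.default_rng(7)
    dense = rng.poisson(1.0, size=(50, 40)) * (rng.random((50, 40)) < 0.6)
    genes = [f"mt-G{i}" if i < 5 else f"G{i}" for i in range(50)]
    cells = [f"c{i}" for i in range(40)]
    return ExpressionMatrix(sp.csr_matrix(dense), genes, cells, layer="raw")
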