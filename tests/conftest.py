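import numpy as np
import pytest

from lsgrn import ExpressionMatrix, MIMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expr(values, gene_ids=None, labels=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    labels = labels or [f"t{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, values, labels)


def make_mi(matrix, gene_ids=None) -> MIMatrix:
    matrix = np.asarray(matrix, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(matrix.shape[0])]
    return MIMatrix(gene_ids, matrix)


def random_symmetric_mi(n, rng, scale=1.0) -> MIMatrix:
    vals = rng.uniform(0, scale, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return make_mi(vals)
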