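import numpy as np
import pandas as pd
import pytest

from samgsr.io_genesets import ExpressionDataset, GeneSetCollection


def make_dataset(values: np.ndarray, n_diseased: int,
                 gene_ids=None, sample_ids=None) -> ExpressionDataset:
    """Wrap a raw genes x samples array; first ``n_diseased`` columns are +1."""
    G, n = values.shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(G)]
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n)]
    labels = pd.Series([1] * n_diseased + [-1] * (n - n_diseased),
                       index=sample_ids)
    return ExpressionDataset(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), labels
    )


def random_dataset(seed: int, G: int = 10, n_d: int = 4, n_c: int = 4,
                   shift_first: float = 0.0) -> ExpressionDataset:
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((G, n_d + n_c))
    if shift_first:
        X[0, :n_d] += shift_first
    return make_dataset(X, n_d)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 6 samples (3 diseased, 3 control) with a clear marker."""
    values = np.array([
        [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],   # shifted up in diseased
        [1.0, 2.0, 1.5, 1.2, 1.8, 1.4],   # noise
        [0.0, 0.5, -0.5, 0.2, -0.2, 0.1], # noise
    ])
    return make_dataset(values, 3, gene_ids=["mark", "n1", "n2"])


@pytest.fixture
def tiny_collection() -> GeneSetCollection:
    return GeneSetCollection(sets={"SIG": ["mark", "n1"], "NULL": ["n1", "n2"]})
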