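import numpy as np
import pytest

from fisherset import ExpressionMatrix


def make_matrix(K=8, n1=6, n2=6, seed=0, shift=0.0, sigma=1.0):
    """Two-group normal expression matrix with an optional group-2 shift."""
    rng = np.random.default_rng(seed)
    values = sigma * rng.standard_normal((K, n1 + n2))
    values[:, n1:] += shift
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(K)],
        sample_ids=[f"s{j}" for j in range(n1 + n2)],
        group_labels=np.array(["a"] * n1 + ["b"] * n2),
    )


@pytest.fixture
def small_mat():
    return make_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
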