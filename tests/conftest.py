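import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gliaxis.containers import ExpressionMatrix


def make_matrix(counts, genes=None, observations=None, obs_meta=None) -> ExpressionMatrix:
    counts = np.asarray(counts, dtype=float)
    n_genes, n_obs = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    observations = observations or [f"c{j}" for j in range(n_obs)]
    return ExpressionMatrix(
        genes=genes,
        observations=observations,
        counts=sp.csr_matrix(counts),
        obs_meta=obs_meta if obs_meta is not None else pd.DataFrame(),
    )


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def random_count_matrix():
    def _make(n_genes, n_obs, seed, density=0.4, max_count=20):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, max_count, size=(n_genes, n_obs)).astype(float)
        counts[rng.random((n_genes, n_obs)) > density] = 0
        return make_matrix(counts)

    return _make
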