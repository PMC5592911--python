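import numpy as np
import pytest

from isovct import DesignVector, IsoformCountMatrix


def make_gene(counts, gene_id="g1"):
    """IsoformCountMatrix from a plain samples x isoforms array."""
    counts = np.atleast_2d(np.asarray(counts))
    n, p = counts.shape
    return IsoformCountMatrix(
        counts=counts,
        sample_ids=tuple(f"s{i}" for i in range(n)),
        isoform_ids=tuple(f"iso{j}" for j in range(p)),
        gene_id=gene_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def balanced_design():
    def _make(n, n_cases=None):
        n_cases = n // 2 if n_cases is None else n_cases
        x = np.zeros(n)
        x[:n_cases] = 1.0
        return DesignVector(x)
    return _make


@pytest.fixture
def random_gene(rng):
    """Small random Poisson-ish gene for structural tests."""
    def _make(n=6, p=3, mean=5.0, seed=None):
        local = rng if seed is None else np.random.default_rng(seed)
        return make_gene(local.poisson(mean, size=(n, p)))
    return _make
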