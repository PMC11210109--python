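import numpy as np
import pytest

from consig import (
    ModalityDistribution,
    SignatureVector,
    default_realistic_bank,
)
from consig.signature_model import default_gene_ids


@pytest.fixture(scope="session")
def bank():
    return default_realistic_bank()


@pytest.fixture(scope="session")
def omega():
    return ModalityDistribution(omega=(0.07, 0.80, 0.13))


@pytest.fixture
def random_signature_pair():
    """Factory for small random signature pairs on a shared gene universe."""

    def make(n_genes=100, seed=0):
        rng = np.random.default_rng(seed)
        ids = default_gene_ids(n_genes)
        a = SignatureVector(gene_ids=ids, lfc=rng.normal(0, 1.5, n_genes))
        b = SignatureVector(gene_ids=ids, lfc=rng.normal(0, 1.5, n_genes))
        return a, b

    return make
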