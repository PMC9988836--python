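import numpy as np
import pandas as pd
import pytest

from modmap.datatypes import GenotypeMatrix


def make_matrix(calls, strains=None, chrom="6", positions=None):
    """Build a small GenotypeMatrix from a (n_variants, n_strains) array."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    strains = strains or [f"S{j + 1}" for j in range(n)]
    positions = positions or list(range(100, 100 + 1000 * m, 1000))
    variants = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(m)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(variants, strains, calls)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[0, 1], [1, -1], [0, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
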