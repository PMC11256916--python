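import numpy as np
import pytest

from scgraphdec.types import ContactMap, NormState


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric_map(rng, n=20, chrom="t", density=1.0, scale=10.0):
    m = rng.random((n, n)) * scale
    if density < 1.0:
        m *= rng.random((n, n)) < density
    m = np.triu(m)
    m = m + np.triu(m, 1).T
    return ContactMap(chrom=chrom, resolution=50_000, matrix=m, norm_state=NormState.RAW)


@pytest.fixture
def random_map(rng):
    return random_symmetric_map(rng)
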