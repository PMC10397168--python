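import numpy as np
import pytest

import pocusqa as pq


@pytest.fixture(scope="session")
def triplicate():
    """Default CIRS-like phantom: three replicate images + mask + truth."""
    spec = pq.default_spec(seed=0)
    images, mask, truth = pq.generate_triplicate(spec)
    return spec, images, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
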