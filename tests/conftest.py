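import numpy as np
import pytest

from dualddi import standard_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """40 drugs / 300 noiseless planted-rule pairs, shared across tests."""
    records, pairs, manifest = standard_benchmark("tiny", seed=7)
    return records, pairs, manifest
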