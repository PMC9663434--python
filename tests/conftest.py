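import numpy as np
import pytest

from spikeweave.topology import Connectivity


@pytest.fixture
def empty_conn():
    """Connectivity with no synapses at all."""
    return Connectivity(
        pre=np.empty(0, dtype=int),
        post=np.empty(0, dtype=int),
        kind=np.empty(0, dtype=np.int8),
        weight=np.empty(0),
        r=np.empty(0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
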