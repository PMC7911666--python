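import numpy as np
import pytest

from replikit import GenomeLayout


@pytest.fixture
def small_layout():
    """Two small chromosomes, one with a partial final bin and segment."""
    return GenomeLayout([("chr1", 1_000_000), ("chr2", 407_500)])


@pytest.fixture
def ten_mb_layout():
    return GenomeLayout([("chr1", 10_000_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)
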