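import numpy as np
import pytest

from prftone.encoding import HDRParams
from prftone.stimulus import build_random_sequence, rasterize


@pytest.fixture(scope="session")
def hdr():
    return HDRParams(shape_k=3, tau=1.5, delay=2.0)


@pytest.fixture(scope="session")
def small_stim():
    """A small mapping scan: 24 geometric frequencies, one pause."""
    seq = build_random_sequence(n_freqs=24, f_min=88, f_max=8000, rng_seed=3,
                                blocks_per_pause=12)
    return rasterize(seq, tr=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
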