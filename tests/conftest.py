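import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from dtilink.similarity import BitFingerprint


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_fingerprints(rng):
    """100 random fingerprint pairs of varying density."""
    pairs = []
    for _ in range(100):
        da, db = rng.uniform(0.05, 0.6, size=2)
        a = BitFingerprint(rng.random(166) < da)
        b = BitFingerprint(rng.random(166) < db)
        pairs.append((a, b))
    return pairs
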