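import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from enhancerkit.io import SequenceRecord


def random_records(rng, n, min_len=30, max_len=200, length=None):
    """Uniformly random ACGT records (shared helper, seeded by caller)."""
    out = []
    for i in range(n):
        L = length if length is not None else int(rng.integers(min_len, max_len + 1))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
        out.append(SequenceRecord(f"r{i:04d}", seq))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_records(rng):
    return random_records(rng, 12, length=50)
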