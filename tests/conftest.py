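import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from pqclan.simulate import random_unrooted_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20110720)


@pytest.fixture
def random_tree_factory():
    """Random binary trees with leaves L0..Ln-1, seeded per call."""

    def make(n_leaves: int, seed: int):
        gen = np.random.default_rng(seed)
        return random_unrooted_tree([f"L{i}" for i in range(n_leaves)], gen)

    return make
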