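import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import exprshift as es


@pytest.fixture(scope="session")
def toy6():
    return es.fixture_toy6()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_tree(n_tips: int, seed: int, clock: bool = False) -> es.PhyloTree:
    """Random non-clock (or ultrametric) tree for property tests."""
    t = es.gen_yule_tree(n_tips, seed=seed, normalize_depth=True)
    if clock:
        return t
    return es.gen_sequence_tree(t, rate_heterogeneity=0.7, seed=seed + 1)
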