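import itertools

import numpy as np
import pandas as pd
import pytest

from panstrata.fixtures import bacterial_fixture, plant_fixture


@pytest.fixture(scope="session")
def plant():
    """8-leaf plant-style chronogram and its MRCA-ladder scheme."""
    return plant_fixture()


@pytest.fixture(scope="session")
def bacterial():
    """8-leaf bacterial-style chronogram and its predicate scheme."""
    return bacterial_fixture()


def all_nonempty_patterns(leaves):
    """All 2^n - 1 nonempty presence patterns over the given leaves."""
    leaves = sorted(leaves)
    for bits in itertools.product([0, 1], repeat=len(leaves)):
        if any(bits):
            yield dict(zip(leaves, bits))


@pytest.fixture()
def null_counts():
    """A small null NB count matrix (no true differences), 5 vs 5."""
    rng = np.random.default_rng(42)
    mu = np.exp(rng.uniform(np.log(50), np.log(500), 400))
    a = 0.1
    counts = rng.negative_binomial(1 / a, 1 / (1 + a * np.tile(mu[:, None], (1, 10))))
    cols = [f"s{i}" for i in range(10)]
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(400)], columns=cols)
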