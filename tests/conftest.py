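import numpy as np
import pytest

from prezone.datasets import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(rng, n=20, m=3, egg_range=(40, 140), stage="s", prefix="o",
                 validation=True):
    scores = rng.normal(2.0, 0.6, size=(n, m))
    eggs = rng.integers(*egg_range, size=n) if validation else None
    return Dataset([f"{prefix}{i}" for i in range(n)], scores,
                   [f"v{p}" for p in range(m)], stage, eggs)


@pytest.fixture
def small_known(rng):
    return make_dataset(rng, n=15, m=2)


@pytest.fixture
def small_unknown(rng):
    return make_dataset(rng, n=12, m=2, validation=False, prefix="u")
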