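import numpy as np
import pytest

from hetmcet import Histogram


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240815)


def random_histogram(
    rng: np.random.Generator,
    n_levels: int = 16,
    max_count: int = 20,
    level_range: tuple = (0, 256),
) -> Histogram:
    """A sparse random histogram with ``n_levels`` occupied gray bins."""
    lo, hi = level_range
    levels = rng.choice(np.arange(lo, hi), size=n_levels, replace=False)
    counts = np.zeros(256, dtype=np.int64)
    counts[levels] = rng.integers(1, max_count + 1, size=n_levels)
    return Histogram(counts)


@pytest.fixture
def histogram_factory():
    return random_histogram
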