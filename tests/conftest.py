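import numpy as np
import pytest

from aistext.preprocess import CleanDocument


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def count_fixture_20():
    """Deterministic 20-point (y, x) count fixture for oracle comparisons."""
    rng = np.random.default_rng(7)
    x = rng.integers(0, 4, size=20).astype(float)
    y = rng.poisson(np.exp(0.2 + 0.5 * x))
    return y.astype(float), x


@pytest.fixture
def toy_docs():
    return [
        CleanDocument("d1", ("a", "b", "a")),
        CleanDocument("d2", ("b",)),
    ]
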