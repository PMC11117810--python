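import numpy as np
import pytest
from hypothesis import settings

from fecgsep import make_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture0():
    """Default 4-s, 250-Hz synthetic excerpt (sources + mixed record)."""
    return make_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sparse_spike_sources(n: int, rng: np.random.Generator) -> np.ndarray:
    """Two disjoint-support, zero-mean sparse spike trains: the regime in
    which ICA parameter recovery is essentially exact (all empirical
    cross-moments vanish)."""
    s = np.zeros((2, n))
    k = max(5, n // 50)
    pos = rng.choice(n, size=2 * k, replace=False)
    for i in range(2):
        s[i, pos[i * k : (i + 1) * k]] = rng.uniform(
            0.5, 1.5, size=k
        ) * rng.choice([-1.0, 1.0], size=k)
    return s
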