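import numpy as np
import pytest

from nnindep.exact_distribution import brute_force_distribution


@pytest.fixture(scope="session")
def bf_laws():
    """Exhaustively enumerated joint distance laws for small n (the oracle)."""
    return {n: brute_force_distribution(n) for n in range(3, 9)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
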