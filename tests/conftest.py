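import numpy as np
import pytest

from neurotherm.core_markov import RateMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_rate_matrix(rng, n, low=0.1, high=2.0) -> RateMatrix:
    w = rng.uniform(low, high, (n, n))
    np.fill_diagonal(w, 0.0)
    return RateMatrix(tuple(range(n)), w)


def random_prob(rng, n):
    p = rng.random(n)
    return p / p.sum()
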