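import numpy as np
import pytest

from netkl import karate_fixture


def random_symmetric(rng, n, *, zero_diagonal=True, density=1.0):
    """Random non-negative symmetric test matrix."""
    A = rng.random((n, n))
    if density < 1.0:
        A *= rng.random((n, n)) < density
    A = np.triu(A) + np.triu(A, 1).T
    if zero_diagonal:
        np.fill_diagonal(A, 0.0)
    if A.sum() == 0:
        A[0, 1] = A[1, 0] = 1.0
    return A


@pytest.fixture(scope="session")
def karate():
    return karate_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
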