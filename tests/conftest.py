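import numpy as np
import pytest

from imotiv import Categorical, JointDistribution, make_gridworld, make_random_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_joint():
    """Factory for seeded random joint distributions of a given shape."""

    def make(nx, ny, seed):
        r = np.random.default_rng(seed)
        J = r.dirichlet(np.ones(nx * ny)).reshape(nx, ny)
        return JointDistribution(J)

    return make


@pytest.fixture
def random_model():
    """Factory for seeded random generative models (defaults kept small)."""

    def make(n_states=4, n_obs=3, n_controls=2, concentration=1.0, seed=0):
        return make_random_model(n_states, n_obs, n_controls,
                                 concentration=concentration, seed=seed)

    return make


@pytest.fixture
def grid3x3():
    """Noiseless 3x3 gridworld without absorbing cells."""
    return make_gridworld(3, 3)


@pytest.fixture
def grid3x3_absorbing_center():
    return make_gridworld(3, 3, absorbing_cells=[4])


def brute_entropy(p):
    """Independent scalar-loop entropy oracle."""
    import math
    total = 0.0
    for x in np.asarray(p, dtype=float):
        if x > 0:
            total -= x * math.log(x)
    return total


def brute_kl(p, q):
    import math
    total = 0.0
    for a, b in zip(np.asarray(p, float), np.asarray(q, float)):
        if a > 0:
            total += a * math.log(a / b)
    return total


def brute_mi(J):
    """Independent scalar-loop mutual-information oracle."""
    import math
    J = np.asarray(J, dtype=float)
    px = J.sum(axis=1)
    py = J.sum(axis=0)
    total = 0.0
    for i in range(J.shape[0]):
        for j in range(J.shape[1]):
            if J[i, j] > 0:
                total += J[i, j] * math.log(J[i, j] / (px[i] * py[j]))
    return total
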