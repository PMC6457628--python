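import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_problem(rng):
    """Random regression problem with n > p (full-rank OLS limit exists)."""
    X = rng.normal(size=(40, 8))
    Y = rng.normal(size=(40, 3))
    return X, Y


def make_sparse_signal(rng, n=60, p=100, k_signal=5, amp=3.0):
    """Data where only the first ``k_signal`` voxels carry class signal."""
    labels = np.tile([1, 2], n // 2)
    X = rng.normal(size=(n, p))
    for j in range(k_signal):
        X[:, j] += amp * (labels == 1)
    return X, labels


@pytest.fixture(scope="session")
def tiny_study():
    """Small simulated study for fast end-to-end tests (48x48 grid)."""
    from plsdecode.simulator import generate_study

    return generate_study(
        cnr_levels=(0.0, 0.4), n_subjects=2, seed=99, shape=(48, 48)
    )
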