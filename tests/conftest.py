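import numpy as np
import pytest

from wmiclust.kernels import KernelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240351)


@pytest.fixture
def blobs():
    """Two tiny, hugely separated Gaussian blobs: the clustering is forced."""
    r = np.random.default_rng(7)
    a = r.normal(0, 0.1, size=(20, 2)) + np.array([10.0, 10.0])
    b = r.normal(0, 0.1, size=(20, 2)) - np.array([10.0, 10.0])
    X = np.vstack([a, b])
    y = np.array([1] * 20 + [2] * 20)
    return X, y


@pytest.fixture
def linear_kernel():
    """Polynomial degree-1, coef0=0: the plain dot-product (Lloyd) kernel."""
    return KernelSpec("polynomial", {"degree": 1, "coef0": 0.0})


def random_contingency(rng, max_rows=4, max_cols=4, max_total=40):
    """A random nonempty contingency table as a count matrix."""
    r = rng.integers(1, max_rows + 1)
    c = rng.integers(1, max_cols + 1)
    counts = rng.integers(0, max_total // (r * c) + 2, size=(r, c))
    if counts.sum() == 0:
        counts[rng.integers(r), rng.integers(c)] = 1
    return counts
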