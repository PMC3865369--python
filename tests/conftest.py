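import numpy as np
import pytest

from jcggm.joint import FitConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fast_cfg():
    """Coarser lambda grid for end-to-end tests; selection behaviour is the
    same, just at reduced path resolution."""
    return FitConfig(n_lambdas=16, lam_ratio=1e-3, bic_patience=5)


def random_spd(rng, p, n=None):
    """Random sample-covariance-like SPD matrix."""
    n = n or 4 * p
    A = rng.standard_normal((n, p))
    return A.T @ A / n
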