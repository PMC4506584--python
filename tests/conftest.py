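import numpy as np
import pytest

from epijack.core import Cov4, JointGenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


def random_pd_cov(rng: np.random.Generator, scale: float = 1.0) -> Cov4:
    """A random well-conditioned 4x4 SPD covariance."""
    A = rng.standard_normal((4, 4))
    return Cov4(V=scale * (A @ A.T + 0.5 * np.eye(4)), provenance="analytic")


def random_positive_table(rng: np.random.Generator, n: float = 900.0) -> JointGenotypeTable:
    """A random all-positive 3x3 table with total mass about n."""
    p = rng.dirichlet(np.full(9, 5.0))
    return JointGenotypeTable(counts=(n * p).reshape(3, 3) + 0.5)
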