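import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from fsda.core_da import LabelledFeatures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_pair(rng):
    """Two well-separated Gaussian clouds sharing a covariance, M=8."""
    m = 8
    import oracles

    cov = oracles.random_spd(rng, m)
    chol = np.linalg.cholesky(cov)
    mu1 = rng.normal(size=m)
    mu2 = mu1 + rng.normal(size=m)
    n = 60
    x1 = mu1 + rng.normal(size=(n, m)) @ chol.T
    x2 = mu2 + rng.normal(size=(n, m)) @ chol.T
    return LabelledFeatures(
        matrix=np.vstack([x1, x2]), labels=np.repeat([1, 2], n)
    )


@pytest.fixture
def hand_case():
    """Tiny two-point-per-class dataset with hand-checkable statistics."""
    return LabelledFeatures(
        matrix=np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0], [1.0, 3.0]]),
        labels=np.array([1, 1, 2, 2]),
    )
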