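import numpy as np
import pytest

from triclust.matnorm_mixture import (
    ComponentParams,
    CovarianceSpec,
    MatrixMixtureModel,
    ar1_correlation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_correlation(t: int, rng: np.random.Generator) -> np.ndarray:
    """Random positive-definite correlation matrix."""
    a = rng.normal(size=(t, t + 2))
    cov = a @ a.T + t * np.eye(t)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


@pytest.fixture
def two_component_model():
    """Well-separated 2-component model, J=2, Tc=3."""
    t = 3
    comps = [
        ComponentParams(M=np.full((2, t), -2.0), sigma2=np.array([0.2, 0.3]),
                        psi=ar1_correlation(0.5, t), rho=0.5),
        ComponentParams(M=np.full((2, t), 2.0), sigma2=np.array([0.25, 0.15]),
                        psi=ar1_correlation(0.2, t), rho=0.2),
    ]
    return MatrixMixtureModel(K=2, pi=np.array([0.4, 0.6]), components=comps,
                              spec=CovarianceSpec(column_structure="ar1"))


@pytest.fixture
def three_component_model():
    """3 components, J=2, Tc=4, separation >= 2 within-component sd."""
    t = 4
    means = [np.zeros((2, t)), np.full((2, t), 2.5),
             np.vstack([np.full(t, -2.5), np.full(t, 2.5)])]
    comps = [
        ComponentParams(M=means[k], sigma2=np.array([0.3, 0.4]),
                        psi=ar1_correlation(0.4, t), rho=0.4)
        for k in range(3)
    ]
    return MatrixMixtureModel(K=3, pi=np.array([0.3, 0.3, 0.4]), components=comps,
                              spec=CovarianceSpec(column_structure="ar1"))


def assert_monotone_trace(trace, slack=1e-8):
    diffs = np.diff(np.asarray(trace))
    assert np.all(diffs >= -slack), f"log-likelihood decreased by {-diffs.min():.3e}"
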