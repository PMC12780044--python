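import numpy as np
import pytest

from tpskit.toy_systems import DiscreteChainSpec, make_double_well_1d, make_two_channel_2d


@pytest.fixture(scope="session")
def double_well():
    return make_double_well_1d(5.0, 2.0)


@pytest.fixture(scope="session")
def two_channel():
    return make_two_channel_2d()


@pytest.fixture(scope="session")
def hop_chain():
    """Five-site birth-death chain used as the exact TPS oracle substrate."""
    return DiscreteChainSpec.uniform(5, p_right=0.55, p_stay=0.0)


class LinearCommittor:
    """Planted analytic committor phi = sigmoid(x . v + b) with exact gradients."""

    def __init__(self, v, b=0.0):
        self.v = np.asarray(v, dtype=float)
        self.b = float(b)

    def logit(self, X):
        return np.atleast_2d(X) @ self.v + self.b

    def predict(self, X):
        from scipy.special import expit

        return expit(self.logit(X))

    def input_gradient(self, X):
        p = self.predict(X)
        return (p * (1 - p))[:, None] * self.v[None, :]


class RadialCommittor:
    """Negative control: phi = sigmoid(|x| - r0), gradients point radially."""

    def __init__(self, r0=1.0):
        self.r0 = float(r0)

    def logit(self, X):
        return np.linalg.norm(np.atleast_2d(X), axis=1) - self.r0

    def predict(self, X):
        from scipy.special import expit

        return expit(self.logit(X))

    def input_gradient(self, X):
        X = np.atleast_2d(X)
        r = np.maximum(np.linalg.norm(X, axis=1), 1e-12)
        p = self.predict(X)
        return (p * (1 - p) / r)[:, None] * X


@pytest.fixture(scope="session")
def linear_committor_cls():
    return LinearCommittor


@pytest.fixture(scope="session")
def radial_committor_cls():
    return RadialCommittor
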