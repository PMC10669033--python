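import numpy as np
import pytest

from meddiffusion import linear_beta_schedule
from meddiffusion.phantoms import PhantomSpec, generate_phantoms


class OracleEpsilonPredictor:
    """Cheating predictor: returns the noise realization consistent with the
    current state, eps = (x_t - sqrt(ab_t) x0) / sqrt(1 - ab_t)."""

    def __init__(self, x0, schedule):
        self.x0 = np.asarray(x0, dtype=np.float64)
        self.s = schedule

    def predict(self, xt, y, t):
        t = int(np.atleast_1d(t)[0])
        ab = self.s.alpha_bar(t)
        x0 = self.x0
        if np.asarray(xt).ndim == 3 and x0.ndim == 2:
            x0 = x0[None]
        return (np.asarray(xt) - np.sqrt(ab) * x0) / np.sqrt(1.0 - ab)


class FixedEpsilonPredictor:
    """Returns one fixed array regardless of inputs."""

    def __init__(self, eps):
        self.eps = np.asarray(eps, dtype=np.float64)

    def predict(self, xt, y, t):
        if np.asarray(xt).ndim == 3 and self.eps.ndim == 2:
            return np.broadcast_to(self.eps, np.asarray(xt).shape).copy()
        return self.eps.copy()


class ZeroPredictor:
    def predict(self, xt, y, t):
        return np.zeros_like(np.asarray(xt, dtype=np.float64))


@pytest.fixture(scope="session")
def paper_schedule():
    return linear_beta_schedule(2000, 1e-4, 0.02)


@pytest.fixture(scope="session")
def toy_schedule():
    return linear_beta_schedule(10, 0.1, 0.2)


@pytest.fixture(scope="session")
def small_schedule():
    return linear_beta_schedule(200, 1e-4, 0.02)


@pytest.fixture(scope="session")
def phantom16():
    return generate_phantoms(PhantomSpec(image_size=16, n_images=1, seed=11))[0].image


@pytest.fixture(scope="session")
def phantom_batch64():
    return [
        ph.image
        for ph in generate_phantoms(
            PhantomSpec(image_size=64, n_images=20, seed=5, texture_strength=0.05)
        )
    ]
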