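"""Training objectives and variational-bound diagnostics.

Training uses only the simplified noise-matching loss; the per-term
variational bound (Gaussian KL terms, prior term, discretized decoder
likelihood) is exposed for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import log_ndtr

from .diffusion import mu_theta_from_eps, q_posterior, q_sample, validate_image
from .schedules import NoiseSchedule

__all__ = [
    "VLBTermReport",
    "simple_loss",
    "gaussian_kl",
    "vlb_term",
    "vlb_term_eps_form",
    "lT_term",
    "l0_term",
    "clamp_unit",
    "bin_probabilities",
]


@dataclass
class VLBTermReport:
    t: int
    term_kind: str  # "L0" | "Lt" | "LT"
    value: float  # nats per image
    per_pixel: Optional[np.ndarray] = field(default=None, repr=False)


def simple_loss(model, x0, y, t, eps, s: NoiseSchedule) -> float:
    """Mean-square noise-matching loss at a given (t, eps) draw.

    The squared norm is reduced by the per-pixel mean so the magnitude is
    resolution-independent (a pure rescaling of the gradient).
    """
    x0 = validate_image(x0, "x0")
    xt = q_sample(x0, t, eps, s)
    eps_hat = np.asarray(model.predict(xt, y, t), dtype=np.float64)
    return float(np.mean((np.asarray(eps) - eps_hat) ** 2))


def gaussian_kl(mean1, var1: float, mean2, var2: float) -> float:
    """KL divergence between diagonal Gaussians with scalar variances,
    summed over pixels, in nats."""
    if var1 <= 0.0 or var2 <= 0.0:
        raise ValueError(f"variances must be positive, got ({var1}, {var2})")
    mean1 = np.asarray(mean1, dtype=np.float64)
    mean2 = np.asarray(mean2, dtype=np.float64)
    if mean1.shape != mean2.shape:
        raise ValueError(f"mean shapes differ: {mean1.shape} vs {mean2.shape}")
    n = mean1.size
    per_pixel_const = 0.5 * (np.log(var2 / var1) + var1 / var2 - 1.0)
    quad = 0.5 * np.sum((mean1 - mean2) ** 2) / var2
    return float(n * per_pixel_const + quad)


def vlb_term(model, x0, y, t: int, xt1, s: NoiseSchedule) -> VLBTermReport:
    """KL between the forward posterior at step t and the model's reverse
    Gaussian at step t+1, for 0 < t < T.  Use :func:`l0_term` / :func:`lT_term`
    for the boundary terms."""
    t = int(t)
    if not 0 < t < s.T:
        raise ValueError(f"vlb_term needs 0 < t < T; got t={t} (use l0_term/lT_term)")
    q_mean, q_var = q_posterior(x0, xt1, t, s)
    eps_hat = np.asarray(model.predict(xt1, y, t + 1), dtype=np.float64)
    p_mean = mu_theta_from_eps(xt1, eps_hat, t + 1, s)
    p_var = s.sigma2(t + 1)
    value = gaussian_kl(q_mean, q_var, p_mean, p_var)
    return VLBTermReport(t=t, term_kind="Lt", value=value)


def vlb_term_eps_form(model, x0, y, t: int, eps, s: NoiseSchedule) -> float:
    """Noise-space form of the same term (without its additive constant):
    beta^2 / (2 sigma^2 alpha (1 - alpha_bar)) * ||eps - eps_hat||^2,
    evaluated at x_{t+1} reconstructed from (x0, eps)."""
    t = int(t)
    if not 0 < t < s.T:
        raise ValueError(f"needs 0 < t < T; got t={t}")
    xt1 = q_sample(x0, t + 1, eps, s)
    eps_hat = np.asarray(model.predict(xt1, y, t + 1), dtype=np.float64)
    beta = s.beta(t + 1)
    alpha = s.alpha(t + 1)
    ab = s.alpha_bar(t + 1)
    coef = beta**2 / (2.0 * s.sigma2(t + 1) * alpha * (1.0 - ab))
    return float(coef * np.sum((np.asarray(eps) - eps_hat) ** 2))


def lT_term(x0, s: NoiseSchedule) -> float:
    """KL(q(x_T | x0) || N(0, I)) in nats per image; a training-free
    diagnostic of how completely the forward chain destroys the signal."""
    x0 = validate_image(x0, "x0")
    ab = s.alpha_bar(s.T)
    mean = np.sqrt(ab) * x0
    return gaussian_kl(mean, 1.0 - ab, np.zeros_like(x0), 1.0)


def clamp_unit(x):
    """Clamp to [-1, 1] (the decoder's integration-limit map)."""
    return np.clip(x, -1.0, 1.0)


def _log_gauss_cdf_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) for a < b, stable in both tails."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    # Work in whichever tail keeps the larger log-mass; exploit symmetry
    # Phi(b) - Phi(a) = Phi(-a) - Phi(-b).
    use_upper = (a + b) > 0.0
    lo = np.where(use_upper, -b, a)
    hi = np.where(use_upper, -a, b)
    log_hi = log_ndtr(hi)
    log_lo = log_ndtr(lo)
    with np.errstate(divide="ignore"):
        diff = np.where(
            log_lo == -np.inf, log_hi, log_hi + np.log1p(-np.exp(log_lo - log_hi))
        )
    return diff


def _per_pixel_log_probs(mu, sigma, x0, delta, edge_mode) -> np.ndarray:
    mu = np.asarray(mu, dtype=np.float64)
    x0 = np.asarray(x0, dtype=np.float64)
    lower = x0 - delta
    upper = x0 + delta
    if edge_mode == "literal":
        # integration limits clamped to [-1, 1]; edge bins lose tail mass
        a = (clamp_unit(lower) - mu) / sigma
        b = (clamp_unit(upper) - mu) / sigma
        return _log_gauss_cdf_diff(a, b)
    if edge_mode == "open":
        a = (lower - mu) / sigma
        b = (upper - mu) / sigma
        logp = _log_gauss_cdf_diff(a, b)
        # lowest bin extends to -inf, highest to +inf: normalized likelihood
        low_edge = lower <= -1.0 + 1e-12
        high_edge = upper >= 1.0 - 1e-12
        logp = np.where(low_edge, log_ndtr(b), logp)
        logp = np.where(high_edge, log_ndtr(-a), logp)
        return logp
    raise ValueError(f"unknown edge_mode {edge_mode!r}")


def l0_term(mu, sigma: float, x0, delta: float = 1.0 / 255.0, edge_mode: str = "open") -> float:
    """Negative log-likelihood of the discretized Gaussian decoder, in nats.

    Each pixel of ``x0`` (on the 8-bit lattice mapped into [-1, 1]) is scored
    by the Gaussian mass of its width-``2*delta`` quantization bin around the
    predicted mean.  CDF differences are computed in log space so variances
    as small as 1e-8 remain finite.

    ``edge_mode="open"`` extends the two edge bins to +-infinity (a proper,
    normalized likelihood); ``"literal"`` clamps the integration limits to
    [-1, 1], losing the tail mass.
    """
    if delta <= 0.0:
        raise ValueError(f"delta must be positive, got {delta}")
    if sigma <= 0.0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    mu = np.asarray(mu, dtype=np.float64)
    x0 = np.asarray(x0, dtype=np.float64)
    if mu.shape != x0.shape:
        raise ValueError(f"mu shape {mu.shape} != x0 shape {x0.shape}")
    logp = _per_pixel_log_probs(mu, sigma, x0, delta, edge_mode)
    return float(-np.sum(logp))


def bin_probabilities(
    mu: float, sigma: float, n_bins: int = 256, edge_mode: str = "open"
) -> np.ndarray:
    """Probability of each 8-bit quantization bin under the decoder.

    Bin centers are the 8-bit lattice mapped to [-1, 1]; with "open" edges
    the probabilities sum to 1 for any (mu, sigma).
    """
    centers = np.arange(n_bins) / (n_bins - 1) * 2.0 - 1.0
    delta = 1.0 / (n_bins - 1)
    logp = _per_pixel_log_probs(
        np.full(n_bins, mu), sigma, centers, delta, edge_mode
    )
    return np.exp(logp)
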