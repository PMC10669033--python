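"""Forward noising, forward posterior, reverse step, and ancestral sampling.

Images are plain float64/float32 numpy arrays of shape (H, W) or batched
(B, H, W).  Clean images live in [-1, 1]; noised intermediates are unbounded.
Every operation is pure given its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .schedules import NoiseSchedule, posterior_coefficients

__all__ = [
    "ReverseStepResult",
    "validate_image",
    "q_sample",
    "q_sample_stepwise",
    "q_posterior",
    "mu_theta_from_eps",
    "predicted_x0_from_eps",
    "p_sample_step",
    "p_sample_loop",
]


def validate_image(x: np.ndarray, name: str = "image") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim not in (2, 3):
        raise ValueError(f"{name} must be (H, W) or (B, H, W), got shape {x.shape}")
    if x.shape[-1] < 1 or x.shape[-2] < 1:
        raise ValueError(f"{name} must have H, W >= 1, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


@dataclass
class ReverseStepResult:
    """One reverse transition: the Gaussian mean, the drawn sample, and the
    clean-image estimate implied by the predicted noise."""

    mean: np.ndarray
    sample: np.ndarray
    predicted_x0: np.ndarray


def _gather_t(values: np.ndarray, t, x_shape) -> np.ndarray:
    """Index a 1-based per-timestep array with scalar or per-example t."""
    t_arr = np.asarray(t, dtype=np.int64)
    if np.any(t_arr < 1) or np.any(t_arr > len(values)):
        raise IndexError(f"timestep(s) {t} outside 1..{len(values)}")
    out = values[t_arr - 1]
    if t_arr.ndim == 1 and len(x_shape) == 3:
        out = out[:, None, None]
    return out


def q_sample(x0: np.ndarray, t, eps: np.ndarray, s: NoiseSchedule) -> np.ndarray:
    """Closed-form forward draw: sqrt(ab_t) x0 + sqrt(1 - ab_t) eps.

    ``t`` may be a scalar or, for batched ``x0``, a per-example integer array.
    Deterministic given ``eps``.
    """
    x0 = validate_image(x0, "x0")
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != x0.shape:
        raise ValueError(f"eps shape {eps.shape} != x0 shape {x0.shape}")
    ab = _gather_t(s.alpha_bars, t, x0.shape)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def q_sample_stepwise(x0: np.ndarray, t: int, s: NoiseSchedule, rng_seed: int) -> np.ndarray:
    """Apply the one-step noising kernel t times in sequence.

    Test oracle for :func:`q_sample`: equal in distribution, quadratic cost.
    """
    x0 = validate_image(x0, "x0")
    t = int(t)
    if not 1 <= t <= s.T:
        raise IndexError(f"t={t} outside 1..{s.T}")
    rng = np.random.default_rng(rng_seed)
    x = x0
    for i in range(1, t + 1):
        beta_i = s.beta(i)
        eps_i = rng.standard_normal(x.shape)
        x = np.sqrt(1.0 - beta_i) * x + np.sqrt(beta_i) * eps_i
    return x


def q_posterior(
    x0: np.ndarray, xt1: np.ndarray, t: int, s: NoiseSchedule
) -> tuple[np.ndarray, float]:
    """Mean and variance of q(x_t | x_{t+1}, x_0) for t in 0..T-1."""
    x0 = validate_image(x0, "x0")
    xt1 = validate_image(xt1, "xt1")
    if x0.shape != xt1.shape:
        raise ValueError(f"x0 shape {x0.shape} != xt1 shape {xt1.shape}")
    coef_x0, coef_xt1, var = posterior_coefficients(s, t)
    mean = coef_x0 * x0 + coef_xt1 * xt1
    return mean, var


def mu_theta_from_eps(xt: np.ndarray, eps_hat: np.ndarray, t, s: NoiseSchedule) -> np.ndarray:
    """Reverse-process mean from predicted noise:
    (1/sqrt(alpha_t)) (x_t - beta_t / sqrt(1 - ab_t) * eps_hat)."""
    xt = validate_image(xt, "xt")
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if eps_hat.shape != xt.shape:
        raise ValueError(f"eps_hat shape {eps_hat.shape} != xt shape {xt.shape}")
    alpha = _gather_t(s.alphas, t, xt.shape)
    beta = _gather_t(s.betas, t, xt.shape)
    ab = _gather_t(s.alpha_bars, t, xt.shape)
    return (xt - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)


def predicted_x0_from_eps(xt: np.ndarray, eps_hat: np.ndarray, t, s: NoiseSchedule) -> np.ndarray:
    """Invert the closed-form forward draw: (x_t - sqrt(1-ab_t) eps) / sqrt(ab_t)."""
    xt = validate_image(xt, "xt")
    ab = _gather_t(s.alpha_bars, t, xt.shape)
    return (xt - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)


def p_sample_step(
    xt: np.ndarray,
    y: np.ndarray,
    t: int,
    model,
    s: NoiseSchedule,
    rng: Optional[np.random.Generator] = None,
    rng_seed: Optional[int] = None,
    noise_at_final_step: bool = False,
) -> ReverseStepResult:
    """One ancestral step: x_{t-1} = mu_theta(x_t, y, t) + sigma_t z.

    ``z = 0`` at ``t = 1`` by default (no noise when emitting the final
    image) and whenever the schedule's sigma mode is "zero".
    """
    xt = validate_image(xt, "xt")
    y = validate_image(y, "y")
    if y.shape[-2:] != xt.shape[-2:]:
        raise ValueError(f"y spatial shape {y.shape[-2:]} != xt {xt.shape[-2:]}")
    t = int(t)
    if not 1 <= t <= s.T:
        raise IndexError(f"t={t} outside 1..{s.T}")
    eps_hat = np.asarray(model.predict(xt, y, t), dtype=np.float64)
    if eps_hat.shape != xt.shape:
        raise ValueError(
            f"model {type(model).__name__} returned shape {eps_hat.shape}, "
            f"expected {xt.shape}"
        )
    mean = mu_theta_from_eps(xt, eps_hat, t, s)
    x0_hat = predicted_x0_from_eps(xt, eps_hat, t, s)
    sigma = s.sigma(t)
    if sigma > 0.0 and (t > 1 or noise_at_final_step):
        if rng is None:
            rng = np.random.default_rng(rng_seed)
        z = rng.standard_normal(xt.shape)
        sample = mean + sigma * z
    else:
        sample = mean.copy()
    return ReverseStepResult(mean=mean, sample=sample, predicted_x0=x0_hat)


def p_sample_loop(
    y: np.ndarray,
    model,
    s: NoiseSchedule,
    rng_seed: int,
    keep_trajectory: bool = False,
    progress: Optional[Callable[[int], None]] = None,
):
    """Full ancestral sampling: draw x_T ~ N(0, I), iterate t = T..1.

    The final image is clipped to [-1, 1]; intermediates are left unclipped.
    Returns the image, or ``(image, trajectory)`` with ``len == T + 1``
    (x_T first, x_0 last) when ``keep_trajectory`` is set.
    """
    y = validate_image(y, "y")
    rng = np.random.default_rng(rng_seed)
    x = rng.standard_normal(y.shape)
    trajectory = [x.copy()] if keep_trajectory else None
    for t in range(s.T, 0, -1):
        step = p_sample_step(x, y, t, model, s, rng=rng)
        x = step.sample
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite sample at timestep t={t}")
        if keep_trajectory:
            trajectory.append(x.copy())
        if progress is not None:
            progress(t)
    x = np.clip(x, -1.0, 1.0)
    if keep_trajectory:
        trajectory[-1] = x.copy()
        return x, trajectory
    return x
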