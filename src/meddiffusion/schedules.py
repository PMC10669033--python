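"""Per-timestep constants of the diffusion process.

A :class:`NoiseSchedule` owns every scalar sequence derived from the forward
variances ``beta``: the signal-retention factors ``alpha``, their cumulative
product ``alpha_bar``, the forward-posterior variance, and the sampling
variance ``sigma2``.  All other modules read these values from here; nothing
recomputes them.

Timesteps are 1-based in the public API (``t = 1..T``).  The empty product
convention ``alpha_bar(0) == 1`` is honoured by the accessor methods.
All sequences are stored in float64: for large ``T`` the cumulative product
underflows quickly in single precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "linear_beta_schedule", "posterior_coefficients"]


@dataclass(frozen=True)
class NoiseSchedule:
    """All per-timestep constants, indexed 1..T via accessor methods.

    The raw arrays (``betas``, ``alphas``, ...) are 0-based: index ``i``
    corresponds to timestep ``t = i + 1``.  Prefer the accessors.
    """

    T: int
    betas: np.ndarray
    alphas: np.ndarray = field(repr=False, default=None)
    alpha_bars: np.ndarray = field(repr=False, default=None)
    posterior_variances: np.ndarray = field(repr=False, default=None)
    sigma2s: np.ndarray = field(repr=False, default=None)
    sigma_mode: str = "beta"

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        betas = np.asarray(self.betas, dtype=np.float64)
        if betas.shape != (self.T,):
            raise ValueError(f"beta must have shape ({self.T},), got {betas.shape}")
        if np.any(betas <= 0.0) or np.any(betas >= 1.0):
            raise ValueError("all beta values must lie in (0, 1)")
        alphas = 1.0 - betas
        alpha_bars = np.cumprod(alphas)
        prev = np.concatenate([[1.0], alpha_bars[:-1]])  # alpha_bar(t-1), with alpha_bar(0)=1
        posterior = (1.0 - prev) / (1.0 - alpha_bars) * betas
        if self.sigma_mode == "beta":
            sigma2s = betas.copy()
        elif self.sigma_mode == "beta_tilde":
            sigma2s = posterior.copy()
        elif self.sigma_mode == "zero":
            sigma2s = np.zeros_like(betas)
        else:
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "alpha_bars", alpha_bars)
        object.__setattr__(self, "posterior_variances", posterior)
        object.__setattr__(self, "sigma2s", sigma2s)

    # -- 1-based accessors -------------------------------------------------

    def _check_t(self, t: int) -> int:
        t = int(t)
        if not 1 <= t <= self.T:
            raise IndexError(f"timestep t={t} outside 1..{self.T}")
        return t

    def beta(self, t: int) -> float:
        return float(self.betas[self._check_t(t) - 1])

    def alpha(self, t: int) -> float:
        return float(self.alphas[self._check_t(t) - 1])

    def alpha_bar(self, t: int) -> float:
        """Cumulative product of alpha up to t; ``alpha_bar(0) == 1``."""
        if t == 0:
            return 1.0
        return float(self.alpha_bars[self._check_t(t) - 1])

    def posterior_variance(self, t: int) -> float:
        return float(self.posterior_variances[self._check_t(t) - 1])

    def sigma2(self, t: int) -> float:
        return float(self.sigma2s[self._check_t(t) - 1])

    def sigma(self, t: int) -> float:
        return float(np.sqrt(self.sigma2(t)))

    def with_sigma_mode(self, mode: str) -> "NoiseSchedule":
        """Same beta sequence, different sampling-variance convention."""
        return NoiseSchedule(T=self.T, betas=self.betas.copy(), sigma_mode=mode)

    def config_dict(self) -> dict:
        """Serializable description: endpoints, never raw arrays."""
        return {
            "T": self.T,
            "beta_start": float(self.betas[0]),
            "beta_end": float(self.betas[-1]),
            "sigma_mode": self.sigma_mode,
        }

    def fingerprint(self) -> str:
        d = self.config_dict()
        return f"linear:T={d['T']}:b1={d['beta_start']:.12g}:bT={d['beta_end']:.12g}:sigma={d['sigma_mode']}"


def linear_beta_schedule(
    T: int,
    beta_start: float = 1e-4,
    beta_end: float = 0.02,
    sigma_mode: str = "beta",
) -> NoiseSchedule:
    """Linearly spaced forward variances from ``beta_start`` to ``beta_end``.

    Defaults are the standard DDPM values (1e-4 to 0.02).  The default
    sampling-variance convention is ``sigma2 == beta``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})"
        )
    betas = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    return NoiseSchedule(T=T, betas=betas, sigma_mode=sigma_mode)


def posterior_coefficients(s: NoiseSchedule, t: int) -> tuple[float, float, float]:
    """Coefficients of the forward posterior q(x_t | x_{t+1}, x_0).

    Returns ``(coef_x0, coef_xt1, var)`` such that the posterior mean is
    ``coef_x0 * x0 + coef_xt1 * x_{t+1}`` and the variance is ``var``.
    Valid for ``t`` in ``0..T-1`` (the ``t = 0`` case uses alpha_bar(0) = 1).
    """
    t = int(t)
    if not 0 <= t <= s.T - 1:
        raise IndexError(f"t={t} outside 0..{s.T - 1} for posterior coefficients")
    ab_t = s.alpha_bar(t)
    ab_t1 = s.alpha_bar(t + 1)
    beta_t1 = s.beta(t + 1)
    alpha_t1 = s.alpha(t + 1)
    denom = 1.0 - ab_t1
    coef_x0 = np.sqrt(ab_t) * beta_t1 / denom
    coef_xt1 = np.sqrt(alpha_t1) * (1.0 - ab_t) / denom
    var = (1.0 - ab_t) / denom * beta_t1
    return float(coef_x0), float(coef_xt1), float(var)
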