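"""Conditional DDPM machinery: noise schedule, forward corruption, Tweedie
single-step denoising, reverse transitions and ancestral sampling.

Conventions.  Timesteps are 1-based externally (t ∈ {1, …, T}); schedule
arrays are 0-based internally (index t−1).  The forward marginal is

    x_t = √ᾱ_t x_0 + √(1 − ᾱ_t) ε,          ε ~ N(0, I),

with α_t = 1 − β_t and ᾱ_t = Π_{s≤t} α_s.  Tweedie's formula inverts it given
a noise estimate, x̂_0 = (x_t − √(1 − ᾱ_t) ε̂) / √ᾱ_t, and the reverse mean is
μ_θ = (x_t − β_t ε̂ / √(1 − ᾱ_t)) / √α_t.  The sampling variance σ_t² is
either β_t or the posterior β̃_t = (1 − ᾱ_{t−1}) β_t / (1 − ᾱ_t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "NoiseSchedule",
    "build_schedule",
    "forward_sample",
    "tweedie_x0",
    "reverse_mean",
    "ancestral_sample",
]


@dataclass(frozen=True)
class NoiseSchedule:
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    beta_tilde: np.ndarray

    @property
    def T(self) -> int:
        return len(self.beta)

    def sigma2(self, variance: str = "beta_tilde") -> np.ndarray:
        if variance == "beta":
            return self.beta
        if variance == "beta_tilde":
            return self.beta_tilde
        raise ValueError(f"unknown variance choice {variance!r}")

    def _check_t(self, t):
        """Validate 1-based step(s); return 0-based index (scalar or array)."""
        t_arr = np.asarray(t)
        if np.any(t_arr < 1) or np.any(t_arr > self.T):
            raise ValueError(f"timestep {t} outside [1, {self.T}]")
        return t - 1 if np.isscalar(t) or t_arr.ndim == 0 else t_arr - 1


def default_beta_range(T: int, reference_T: int = 1000,
                       reference_range: tuple[float, float] = (1e-4, 0.02)) -> tuple[float, float]:
    """β range for a T-step schedule matching the reference chain's total
    corruption.

    The usual linear range (1e-4, 0.02) is calibrated for T = 1000; since
    ᾱ_T ≈ exp(−Σβ_t), a shorter chain must scale β by reference_T/T or its
    terminal state stays far from the N(0, I) prior that sampling starts
    from.  Values are capped at 0.999.
    """
    scale = reference_T / T
    lo, hi = reference_range
    return min(lo * scale, 0.999), min(hi * scale, 0.999)


def build_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02,
                   kind: str = "linear") -> NoiseSchedule:
    """Linear β schedule with all derived arrays computed once."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    alpha_bar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    beta_tilde = (1.0 - alpha_bar_prev) / (1.0 - alpha_bar) * beta
    return NoiseSchedule(beta=beta, alpha=alpha, alpha_bar=alpha_bar, beta_tilde=beta_tilde)


def _per_example(coeff, x) -> np.ndarray:
    """Align a per-example coefficient vector with the trailing axes of x."""
    coeff = np.asarray(coeff)
    if coeff.ndim == 0:
        return coeff
    ndim = x.ndim if hasattr(x, "ndim") else np.asarray(x).ndim
    return coeff.reshape(coeff.shape + (1,) * (ndim - 1))


def forward_sample(x0, t, schedule: NoiseSchedule, eps):
    """Sample x_t from the closed-form forward marginal (reparameterization).

    ``t`` is 1-based and may be a scalar or a per-example integer vector.
    """
    i = schedule._check_t(t)
    ab = _per_example(schedule.alpha_bar[i], x0)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def tweedie_x0(x_t, eps_hat, t, schedule: NoiseSchedule):
    """Single-step denoised estimate x̂_0 = (x_t − √(1−ᾱ_t) ε̂)/√ᾱ_t.

    Works on plain arrays or autodiff tensors (used inside the physics loss,
    where gradients must flow through ε̂).
    """
    i = schedule._check_t(t)
    ab = _per_example(schedule.alpha_bar[i], x_t)
    return (x_t - np.sqrt(1.0 - ab) * eps_hat) * (1.0 / np.sqrt(ab))


def reverse_mean(x_t, eps_hat, t, schedule: NoiseSchedule):
    """Posterior mean parameterization μ_θ = (x_t − β_t ε̂/√(1−ᾱ_t))/√α_t."""
    i = schedule._check_t(t)
    beta = _per_example(schedule.beta[i], x_t)
    ab = _per_example(schedule.alpha_bar[i], x_t)
    alpha = _per_example(schedule.alpha[i], x_t)
    return (x_t - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)


def ancestral_sample(
    model,
    h_phys: np.ndarray,
    schedule: NoiseSchedule,
    seed: int,
    clip_x0: bool = True,
    variance: str = "beta_tilde",
) -> np.ndarray:
    """Generate ECG windows by iterating the reverse chain from x_T ~ N(0, I).

    ``model(x_t, step_index, h_phys)`` takes the 0-based step index t−1 and
    must return an object with an ``eps_hat`` attribute (or the array
    itself).  With ``clip_x0`` the implied clean estimate is clamped to
    [−1, 1] and re-injected into the posterior mean — appropriate because
    training windows are min-max normalized.
    """
    h_phys = np.asarray(h_phys, dtype=np.float64)
    if h_phys.ndim == 2:
        h_phys = h_phys[None]
    n, _, length = h_phys.shape
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, length))
    for t in range(schedule.T, 0, -1):
        i = t - 1
        with ad.no_grad():
            out = model(Tensor(x), t - 1, Tensor(h_phys))
        eps_hat = out.eps_hat.data if hasattr(out, "eps_hat") else np.asarray(out)
        if clip_x0:
            x0_hat = np.clip(tweedie_x0(x, eps_hat, t, schedule), -1.0, 1.0)
            ab, ab_prev = schedule.alpha_bar[i], 1.0 if i == 0 else schedule.alpha_bar[i - 1]
            beta = schedule.beta[i]
            # posterior mean written in terms of (x_t, x̂_0)
            mean = (
                np.sqrt(ab_prev) * beta / (1.0 - ab) * x0_hat
                + np.sqrt(schedule.alpha[i]) * (1.0 - ab_prev) / (1.0 - ab) * x
            )
        else:
            mean = reverse_mean(x, eps_hat, t, schedule)
        if t > 1:
            sigma = np.sqrt(schedule.sigma2(variance)[i])
            x = mean + sigma * rng.standard_normal((n, length))
        else:
            x = mean
    if clip_x0:
        x = np.clip(x, -1.0, 1.0)
    return x
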