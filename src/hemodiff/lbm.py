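"""Differentiable lattice-Boltzmann (D1Q3) hemodynamic encoder.

The PPG window is treated as a 1-D spatial domain carrying a pressure wave.
A learnable lifting layer distributes the scalar signal into Q = 3 kinetic
channels (velocities e ∈ {−1, 0, +1}); the state then evolves by K rounds of
a learned channel-mixing collision — projected so each site conserves mass
and momentum exactly — followed by streaming (a circular shift of each
channel by its lattice velocity).  The macroscopic moments of the evolved
state,

    ρ(x)  = Σ_i F_i(x)          (density, zeroth moment)
    ρu(x) = Σ_i e_i F_i(x)      (momentum, first moment)

are concatenated channel-wise into the conditioning embedding ``h_phys``
consumed by the diffusion backbone.

Moment projection.  Given a raw collision residual C̃ with per-site excesses
Δρ = Σ_i C̃_i and Δm = Σ_i e_i C̃_i, the default ``exact`` projection removes

    C_i = C̃_i − Δρ/Q − e_i Δm / Σ_j e_j²,

which zeroes both moments for any velocity set with Σ e_i = 0.  The
alternative ``paper_literal`` projection uses the coefficient 3 e_i Δm / Q
instead; for D1Q3 that variant does not cancel the momentum excess and is
kept only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Module

__all__ = ["LatticeConfig", "LBMEncoder", "collide_project", "stream", "moments"]


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry and evolution schedule of the encoder."""

    Q: int = 3
    velocities: tuple[int, ...] = (-1, 0, 1)
    stride: int = 1  # samples advected per step and unit velocity
    n_steps: int = 4  # collide–stream iterations K
    projection: str = "exact"  # "exact" | "paper_literal"

    def __post_init__(self):
        if self.Q != len(self.velocities):
            raise ValueError("Q must equal len(velocities)")
        if len(set(self.velocities)) != self.Q:
            raise ValueError("velocities must be distinct")
        if self.projection not in ("exact", "paper_literal"):
            raise ValueError(f"unknown projection {self.projection!r}")
        if self.projection == "exact" and sum(e * e for e in self.velocities) == 0:
            raise ValueError("degenerate velocity set: sum of squared velocities is 0")


def collide_project(F: Tensor, mix_w: Tensor, mix_b: Tensor, cfg: LatticeConfig) -> Tensor:
    """Learned collision with conservation-enforcing moment projection.

    ``F`` has shape (N, Q, L).  The raw residual is a per-site channel-mixing
    linear map (1×1 convolution) of F; the projection subtracts the mass and
    momentum excesses so Σ_i C_i = Σ_i e_i C_i = 0 at every site.
    """
    n, q, length = F.shape
    e = Tensor(np.asarray(cfg.velocities, dtype=np.float64).reshape(1, q, 1))
    # channel mixing: C̃[n,i,l] = Σ_j mix_w[i,j] F[n,j,l] + mix_b[i]
    c_raw = ad.conv1d(F, mix_w.reshape(q, q, 1), mix_b, padding=0)
    d_rho = c_raw.sum(axis=1, keepdims=True)  # (N,1,L)
    d_mom = (c_raw * e).sum(axis=1, keepdims=True)
    if cfg.projection == "exact":
        coeff = e * (1.0 / sum(v * v for v in cfg.velocities))
    else:  # paper_literal: 3 e_i / Q
        coeff = e * (3.0 / cfg.Q)
    c_proj = c_raw - d_rho * (1.0 / cfg.Q) - coeff * d_mom
    return F + c_proj


def stream(F: Tensor, cfg: LatticeConfig) -> Tensor:
    """Advect each channel circularly by stride × velocity (periodic boundary)."""
    chans = []
    for i, e in enumerate(cfg.velocities):
        ch = F[:, i : i + 1, :]
        shift = int(e) * cfg.stride
        chans.append(ad.roll(ch, shift, axis=-1) if shift else ch)
    return ad.concat(chans, axis=1)


def moments(F: Tensor, cfg: LatticeConfig) -> Tensor:
    """Macroscopic readout: h_phys = concat(ρ, ρu) with shape (N, 2, L)."""
    e = Tensor(np.asarray(cfg.velocities, dtype=np.float64).reshape(1, len(cfg.velocities), 1))
    rho = F.sum(axis=1, keepdims=True)
    rho_u = (F * e).sum(axis=1, keepdims=True)
    return ad.concat([rho, rho_u], axis=1)


class LBMEncoder(Module):
    """Lift → K × (collide ∘ stream) → moments, end-to-end differentiable."""

    def __init__(self, cfg: LatticeConfig | None = None, rng: np.random.Generator | None = None):
        self.cfg = cfg or LatticeConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        q = self.cfg.Q
        # lifting: F_i(x) = softplus(w_i c(x) + b_i)
        self.lift_w = Tensor(rng.normal(0.0, 0.5, (q,)), requires_grad=True)
        self.lift_b = Tensor(np.zeros(q), requires_grad=True)
        # collision channel mixing, initialized near-zero so early training is
        # close to pure advection
        self.mix_w = Tensor(rng.normal(0.0, 0.1, (q, q)), requires_grad=True)
        self.mix_b = Tensor(np.zeros(q), requires_grad=True)

    def lift(self, c: Tensor | np.ndarray) -> Tensor:
        """Phase-space lifting; strictly positive by the softplus activation."""
        c = ad.as_tensor(c)
        if c.ndim == 1:
            c = c.reshape(1, -1)
        n, length = c.shape
        q = self.cfg.Q
        x = c.reshape(n, 1, length)
        return ad.softplus(x * self.lift_w.reshape(1, q, 1) + self.lift_b.reshape(1, q, 1))

    def forward(self, c: Tensor | np.ndarray) -> Tensor:
        """Encode a batch of PPG windows (N, L) → h_phys (N, 2, L)."""
        F = self.lift(c)
        for _ in range(self.cfg.n_steps):
            F = collide_project(F, self.mix_w, self.mix_b, self.cfg)
            F = stream(F, self.cfg)
        return moments(F, self.cfg)

    encode = forward
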