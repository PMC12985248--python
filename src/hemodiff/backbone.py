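"""Region-disentangled 1-D denoising U-Net with physics-guided cross-attention.

A shared multiscale encoder–decoder processes the noisy ECG (optionally with
the hemodynamic condition concatenated as input channels) and bifurcates into
two heads:

* the **geometry head** predicts the diffusion noise residual ε̂ (GroupNorm →
  SiLU → convolution), driving waveform reconstruction;
* the **topology head** predicts a per-sample QRS probability mask r̂ ∈ (0,1)
  (convolution → sigmoid), an auxiliary segmentation task that forces the
  shared features to track the cardiac cycle.

At the bottleneck, cross-attention aligns the electrical latents Z (queries)
with the average-pooled hemodynamic features h_phys (keys/values):

    Z' = Z + softmax(Q Kᵀ / √d_k) V,

letting the model compensate for the pulse transit time between the PPG pulse
and the R-peak without a hand-set delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv1d, GroupNorm, Linear, Module

__all__ = ["BackboneConfig", "BackboneOutput", "CrossAttention", "UNet1D", "timestep_embedding"]


@dataclass(frozen=True)
class BackboneConfig:
    length: int = 512
    base_width: int = 32
    n_scales: int = 3
    attention_dim: int = 32
    groups: int = 8
    temb_dim: int = 32
    cond_channels: int = 2  # channels of h_phys (density, momentum)
    concat_condition: bool = True
    n_timesteps: int = 1000

    def __post_init__(self):
        if self.length % (2 ** (self.n_scales - 1)):
            raise ValueError("length must be divisible by 2^(n_scales-1)")
        if self.attention_dim < 1:
            raise ValueError("attention_dim must be >= 1")


@dataclass
class BackboneOutput:
    eps_hat: Tensor  # (N, L) predicted noise
    r_hat: Tensor  # (N, L) QRS probabilities in (0, 1)
    h_dec: Tensor  # (N, C, L) decoder features


def timestep_embedding(t, dim: int, n_timesteps: int) -> np.ndarray:
    """Sinusoidal position encoding of 0-based diffusion steps.

    ``t`` may be a scalar (→ shape (dim,)) or an integer array of per-example
    steps (→ shape (N, dim)).
    """
    t_arr = np.asarray(t)
    if np.any(t_arr < 0) or np.any(t_arr >= n_timesteps):
        raise ValueError(f"timestep {t} outside [0, {n_timesteps})")
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t_arr[..., None] * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)


class ConvBlock(Module):
    """Pre-activation residual block, the standard DDPM design:

    GN → SiLU → conv → (+ time embedding) → GN → SiLU → conv(zero-init),
    plus an identity (or 1×1) shortcut.  The zero-initialized second
    convolution makes each block start as the identity, which keeps early
    training well-conditioned.
    """

    def __init__(self, c_in: int, c_out: int, groups: int, temb_dim: int, rng):
        def fit_groups(c):
            g = min(groups, c)
            while c % g:
                g -= 1
            return g

        self.norm1 = GroupNorm(fit_groups(c_in), c_in)
        self.conv1 = Conv1d(c_in, c_out, 3, rng)
        self.temb_proj = Linear(temb_dim, c_out, rng)
        self.norm2 = GroupNorm(fit_groups(c_out), c_out)
        # near-zero init: the block starts close to the identity while every
        # parameter still receives gradient on the first step
        self.conv2 = Conv1d(c_out, c_out, 3, rng, init_scale=1e-3)
        self.shortcut = None if c_in == c_out else Conv1d(c_in, c_out, 1, rng, padding=0)

    def forward(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(ad.silu(self.norm1(x)))
        c = h.shape[1]
        # temb is (N, D) or (1, D); the projection broadcasts over length
        h = h + self.temb_proj(temb).reshape(-1, c, 1)
        h = self.conv2(ad.silu(self.norm2(h)))
        return h + (x if self.shortcut is None else self.shortcut(x))


class CrossAttention(Module):
    """Single-head cross-attention; the value path maps into the latent width
    so a zero value projection leaves Z exactly unchanged (Z' = Z)."""

    def __init__(self, d_z: int, d_p: int, d_k: int, rng):
        self.d_k = d_k
        self.w_q = Tensor(rng.normal(0, 1 / np.sqrt(d_z), (d_z, d_k)), requires_grad=True)
        self.w_k = Tensor(rng.normal(0, 1 / np.sqrt(d_p), (d_p, d_k)), requires_grad=True)
        self.w_v = Tensor(rng.normal(0, 1 / np.sqrt(d_p), (d_p, d_z)), requires_grad=True)

    def attention_matrix(self, z: Tensor, h: Tensor) -> Tensor:
        """Row-stochastic M = softmax(QKᵀ/√d_k); z (N,L',Dz), h (N,L',Dp)."""
        q = z @ self.w_q
        k = h @ self.w_k
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_k))
        return ad.softmax(scores, axis=-1)

    def forward(self, z: Tensor, h: Tensor) -> Tensor:
        if z.shape[1] != h.shape[1]:
            raise ValueError("latent and condition lengths must match")
        m = self.attention_matrix(z, h)
        v = h @ self.w_v
        return z + m @ v


class UNet1D(Module):
    """Shared encoder–decoder trunk with geometry and topology heads."""

    def __init__(self, cfg: BackboneConfig | None = None, rng: np.random.Generator | None = None):
        self.cfg = cfg or BackboneConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        c = self.cfg
        widths = [c.base_width * 2**i for i in range(c.n_scales)]

        self.temb_mlp1 = Linear(c.temb_dim, c.temb_dim, rng)
        self.temb_mlp2 = Linear(c.temb_dim, c.temb_dim, rng)

        in_ch = 1 + (c.cond_channels if c.concat_condition else 0)
        # the first block's GroupNorm standardizes the raw channels per
        # window, which doubles as input preconditioning across noise levels
        self.enc_blocks = []
        ch = in_ch
        for w in widths:
            self.enc_blocks.append(ConvBlock(ch, w, c.groups, c.temb_dim, rng))
            ch = w

        self.mid_block = ConvBlock(widths[-1], widths[-1], c.groups, c.temb_dim, rng)
        self.attn = CrossAttention(widths[-1], c.cond_channels, c.attention_dim, rng)

        self.dec_blocks = []
        for i in reversed(range(c.n_scales - 1)):
            # input: upsampled deeper features + skip connection
            self.dec_blocks.append(
                ConvBlock(widths[i + 1] + widths[i], widths[i], c.groups, c.temb_dim, rng)
            )

        g = min(c.groups, widths[0])
        while widths[0] % g:
            g -= 1
        self.head_norm = GroupNorm(g, widths[0])
        self.head_noise = Conv1d(widths[0], 1, 3, rng)
        self.head_mask = Conv1d(widths[0], 1, 3, rng)

    def _embed_t(self, t) -> Tensor:
        emb = timestep_embedding(t, self.cfg.temb_dim, self.cfg.n_timesteps)
        if emb.ndim == 1:
            emb = emb[None, :]
        return self.temb_mlp2(ad.silu(self.temb_mlp1(Tensor(emb))))

    def forward(self, x_t: Tensor | np.ndarray, t, h_phys: Tensor | np.ndarray) -> BackboneOutput:
        c = self.cfg
        x_t = ad.as_tensor(x_t)
        h_phys = ad.as_tensor(h_phys)
        if x_t.ndim == 1:
            x_t = x_t.reshape(1, -1)
        if h_phys.ndim == 2:
            h_phys = h_phys.reshape(1, *h_phys.shape)
        n, length = x_t.shape
        if length != c.length:
            raise ValueError(f"expected windows of length {c.length}, got {length}")
        if h_phys.shape[-1] != length or h_phys.shape[1] != c.cond_channels:
            raise ValueError("h_phys must have shape (N, cond_channels, L)")

        temb = self._embed_t(t)
        h = x_t.reshape(n, 1, length)
        if c.concat_condition:
            h = ad.concat([h, h_phys], axis=1)

        skips = []
        for i, block in enumerate(self.enc_blocks):
            h = block(h, temb)
            if i < len(self.enc_blocks) - 1:
                skips.append(h)
                h = ad.avg_pool1d(h, 2)

        h = self.mid_block(h, temb)
        # bottleneck cross-attention against average-pooled hemodynamic features
        factor = 2 ** (c.n_scales - 1)
        h_down = ad.avg_pool1d(h_phys, factor) if factor > 1 else h_phys
        z = h.transpose(0, 2, 1)  # (N, L', D_z)
        z = self.attn(z, h_down.transpose(0, 2, 1))
        h = z.transpose(0, 2, 1)

        for block, skip in zip(self.dec_blocks, reversed(skips)):
            h = ad.upsample_nearest1d(h, 2)
            h = ad.concat([h, skip], axis=1)
            h = block(h, temb)

        h_dec = h
        eps = self.head_noise(ad.silu(self.head_norm(h_dec)))
        r_hat = ad.sigmoid(self.head_mask(h_dec))
        return BackboneOutput(
            eps_hat=eps.reshape(n, length),
            r_hat=r_hat.reshape(n, length),
            h_dec=h_dec,
        )
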