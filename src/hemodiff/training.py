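"""Composite physics-informed objective and the joint training loop.

The total loss is a weighted sum of three terms,

    L = λ_diff ‖ε − ε̂‖²  +  λ_reg BCE(r, r̂)  +  λ_phys ‖∂x̂₀/∂τ − P_φ(h_phys)‖²,

where x̂₀ is the Tweedie single-step denoised estimate and P_φ is a learnable
per-site linear map from the two hemodynamic channels (ρ, ρu) to one channel.
The physics term ties the temporal derivative of the generated ECG to the
momentum flux read out of the lattice encoder, penalizing waveforms whose
evolution is hemodynamically implausible.  Every parameter group — lifting,
collision mixing, backbone trunk, both heads, attention projections and P_φ —
is updated jointly by Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import BackboneConfig, UNet1D
from .diffusion import NoiseSchedule, build_schedule, forward_sample, tweedie_x0
from .lbm import LatticeConfig, LBMEncoder
from .nn import Adam, Module
from .preprocessing import SignalWindow

__all__ = [
    "LossWeights",
    "TrainConfig",
    "PhysicsProjector",
    "TranslationModel",
    "loss_diff",
    "loss_reg",
    "loss_phys",
    "loss_total",
    "temporal_derivative",
    "train_step",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda_diff: float = 1.0
    lambda_reg: float = 0.1
    lambda_phys: float = 0.1

    def __post_init__(self):
        if min(self.lambda_diff, self.lambda_reg, self.lambda_phys) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    steps: int = 500
    batch_size: int = 16
    lr: float = 2e-4
    seed: int = 0
    checkpoint_every: int = 0  # 0: only at the end
    phys_target_detach: bool = False
    sigma_variance: str = "beta_tilde"
    # exponential moving average of parameters, swapped in after training —
    # the standard weight set for diffusion sampling; 0 disables
    ema_decay: float = 0.995

    def __post_init__(self):
        if self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps and batch_size must be positive")


class PhysicsProjector(Module):
    """Per-site linear map P_φ: (N, 2, L) hemodynamic moments → (N, L) flux."""

    def __init__(self, cond_channels: int = 2, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(rng.normal(0, 0.5, (cond_channels,)), requires_grad=True)
        self.bias = Tensor(np.zeros(1), requires_grad=True)

    def forward(self, h_phys: Tensor) -> Tensor:
        n, c, length = h_phys.shape
        w = self.weight.reshape(1, c, 1)
        return (h_phys * w).sum(axis=1) + self.bias


class TranslationModel(Module):
    """Bundle of the three trainable components: encoder, backbone, P_φ."""

    def __init__(self, lattice_cfg: LatticeConfig | None = None,
                 backbone_cfg: BackboneConfig | None = None, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))
        self.lattice_cfg = lattice_cfg or LatticeConfig()
        self.backbone_cfg = backbone_cfg or BackboneConfig()
        self.encoder = LBMEncoder(self.lattice_cfg, rng)
        self.unet = UNet1D(self.backbone_cfg, rng)
        self.projector = PhysicsProjector(self.backbone_cfg.cond_channels, rng)

    def forward(self, x_t: Tensor, t_index: int, h_phys: Tensor):
        return self.unet(x_t, t_index, h_phys)


# -- loss components ------------------------------------------------------


def loss_diff(eps: Tensor | np.ndarray, eps_hat: Tensor) -> Tensor:
    """Denoising score-matching loss: element-mean squared error."""
    eps = ad.as_tensor(eps)
    if eps.shape != eps_hat.shape:
        raise ValueError("eps and eps_hat shapes differ")
    return ((eps_hat - eps) ** 2).mean()


def loss_reg(r: Tensor | np.ndarray, r_hat: Tensor) -> Tensor:
    """Binary cross-entropy of the QRS mask, probabilities clamped at 1e-7."""
    r = ad.as_tensor(r)
    if r.shape != r_hat.shape:
        raise ValueError("mask shapes differ")
    p = ad.clip(r_hat, _BCE_EPS, 1.0 - _BCE_EPS)
    return -(r * p.log() + (1.0 - r) * (1.0 - p).log()).mean()


def temporal_derivative(x: Tensor) -> Tensor:
    """Central finite differences along the last axis, one-sided at edges."""
    n = x.shape[-1]
    interior = (x[..., 2:] - x[..., :-2]) * 0.5
    first = (x[..., 1:2] - x[..., 0:1])
    last = (x[..., n - 1 : n] - x[..., n - 2 : n - 1])
    return ad.concat([first, interior, last], axis=-1)


def loss_phys(x0_hat: Tensor, h_phys: Tensor, projector: PhysicsProjector,
              detach_target: bool = False) -> Tensor:
    """Hemodynamic consistency: MSE between ∂x̂₀/∂τ and P_φ(h_phys)."""
    target_h = h_phys.detach() if detach_target else h_phys
    flux = projector(target_h)
    dx = temporal_derivative(x0_hat)
    if dx.shape != flux.shape:
        raise ValueError("derivative and flux shapes differ")
    return ((dx - flux) ** 2).mean()


def loss_total(l_diff: Tensor, l_reg: Tensor, l_phys: Tensor, weights: LossWeights) -> Tensor:
    return (
        weights.lambda_diff * l_diff
        + weights.lambda_reg * l_reg
        + weights.lambda_phys * l_phys
    )


# -- training loop --------------------------------------------------------


def _batch_arrays(windows: list[SignalWindow]):
    x0 = np.stack([w.ecg for w in windows])
    ppg = np.stack([w.ppg for w in windows])
    mask = np.stack([w.mask for w in windows])
    return x0, ppg, mask


def train_step(
    windows: list[SignalWindow],
    model: TranslationModel,
    schedule: NoiseSchedule,
    weights: LossWeights,
    optimizer: Adam,
    rng: np.random.Generator,
    phys_target_detach: bool = False,
) -> dict[str, float]:
    """One joint optimization step on a batch of windows.

    Per example: draw t ~ U{1..T} and ε ~ N(0, I), corrupt x₀ to x_t, encode
    the PPG, run the backbone, form the Tweedie estimate and the three losses,
    then update all parameters.
    """
    if not windows:
        raise ValueError("batch must be nonempty")
    x0, ppg, mask = _batch_arrays(windows)
    t = rng.integers(1, schedule.T + 1, size=len(windows))
    eps = rng.standard_normal(x0.shape)
    x_t = forward_sample(x0, t, schedule, eps)

    h_phys = model.encoder(Tensor(ppg))
    out = model.unet(Tensor(x_t), t - 1, h_phys)
    x0_hat = tweedie_x0(Tensor(x_t), out.eps_hat, t, schedule)

    l_d = loss_diff(eps, out.eps_hat)
    l_r = loss_reg(mask, out.r_hat)
    l_p = loss_phys(x0_hat, h_phys, model.projector, detach_target=phys_target_detach)
    total = loss_total(l_d, l_r, l_p, weights)
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite loss (t={t.tolist()}): diff={l_d.item()}, "
            f"reg={l_r.item()}, phys={l_p.item()}"
        )

    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return {
        "loss_diff": l_d.item(),
        "loss_reg": l_r.item(),
        "loss_phys": l_p.item(),
        "loss_total": total.item(),
    }


def train(
    windows: list[SignalWindow],
    model: TranslationModel,
    schedule: NoiseSchedule,
    weights: LossWeights | None = None,
    config: TrainConfig | None = None,
    log_fn=None,
    checkpoint_dir: str | Path | None = None,
) -> list[dict[str, float]]:
    """Run the full loop: shuffled minibatches, Adam on every parameter."""
    weights = weights or LossWeights()
    config = config or TrainConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 20]))
    params = model.parameters()
    optimizer = Adam(params, lr=config.lr)
    ema = [p.data.copy() for p in params] if config.ema_decay > 0 else None
    history: list[dict[str, float]] = []
    n = len(windows)
    order = rng.permutation(n)
    cursor = 0
    for step in range(config.steps):
        if cursor + config.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        batch = [windows[j] for j in order[cursor : cursor + config.batch_size]]
        cursor += config.batch_size
        rec = train_step(batch, model, schedule, weights, optimizer, rng,
                         phys_target_detach=config.phys_target_detach)
        rec["step"] = step
        history.append(rec)
        if ema is not None:
            d = config.ema_decay
            for shadow, p in zip(ema, params):
                shadow *= d
                shadow += (1 - d) * p.data
        if log_fn is not None:
            log_fn(rec)
        if checkpoint_dir and config.checkpoint_every and (step + 1) % config.checkpoint_every == 0:
            save_checkpoint(model, schedule, Path(checkpoint_dir) / f"ckpt_{step + 1}.npz")
    if ema is not None:
        for shadow, p in zip(ema, params):
            p.data = shadow.copy()
    if checkpoint_dir:
        save_checkpoint(model, schedule, Path(checkpoint_dir) / "ckpt_final.npz")
    return history


# -- checkpoint I/O -------------------------------------------------------


def save_checkpoint(model: TranslationModel, schedule: NoiseSchedule, path: str | Path) -> None:
    """Single-file parameter archive with the configs embedded as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps(
        {
            "lattice": asdict(model.lattice_cfg),
            "backbone": asdict(model.backbone_cfg),
            "schedule": {
                "T": schedule.T,
                "beta_start": float(schedule.beta[0]),
                "beta_end": float(schedule.beta[-1]),
            },
        }
    )
    state = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[TranslationModel, NoiseSchedule]:
    path = Path(path)
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k.replace("__", "."): npz[k] for k in npz.files if k != "__meta__"}
    lattice_cfg = LatticeConfig(**{**meta["lattice"], "velocities": tuple(meta["lattice"]["velocities"])})
    backbone_cfg = BackboneConfig(**meta["backbone"])
    model = TranslationModel(lattice_cfg, backbone_cfg)
    model.load_state_dict(state)
    schedule = build_schedule(
        meta["schedule"]["T"], meta["schedule"]["beta_start"], meta["schedule"]["beta_end"]
    )
    return model, schedule
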