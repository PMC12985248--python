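"""Small neural-network layer library used by the encoder and backbone.

Layers follow the usual Module convention: parameters are registered
:class:`~hemodiff.autodiff.Tensor` leaves with ``requires_grad=True``,
collected recursively by :meth:`Module.parameters`, and updated in place by
:class:`Adam`.  Initialization draws from an explicit ``numpy.random.Generator``
so a model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, silu

__all__ = ["Module", "Linear", "Conv1d", "GroupNorm", "SiLU", "Sequential", "Adam"]


class Module:
    """Base class: child modules and parameters discovered via attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            items = obj if isinstance(obj, (list, tuple)) else [obj]
            for it in items:
                if isinstance(it, Tensor) and it.requires_grad and id(it) not in seen:
                    seen.add(id(it))
                    params.append(it)
                elif isinstance(it, Module):
                    for p in it.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(mod: "Module", prefix: str) -> None:
            for name, obj in mod.__dict__.items():
                items = obj if isinstance(obj, (list, tuple)) else [obj]
                for i, it in enumerate(items):
                    key = f"{prefix}{name}.{i}" if isinstance(obj, (list, tuple)) else f"{prefix}{name}"
                    if isinstance(it, Tensor) and it.requires_grad:
                        out[key] = it.data.copy()
                    elif isinstance(it, Module):
                        walk(it, key + ".")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def walk(mod: "Module", prefix: str) -> None:
            for name, obj in mod.__dict__.items():
                items = obj if isinstance(obj, (list, tuple)) else [obj]
                for i, it in enumerate(items):
                    key = f"{prefix}{name}.{i}" if isinstance(obj, (list, tuple)) else f"{prefix}{name}"
                    if isinstance(it, Tensor) and it.requires_grad:
                        arr = np.asarray(state[key], dtype=np.float64)
                        if arr.shape != it.data.shape:
                            raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {it.data.shape}")
                        it.data = arr.copy()
                    elif isinstance(it, Module):
                        walk(it, key + ".")

        walk(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.normal(0.0, 1.0, (d_in, d_out)) * scale, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Stride-1 'same' or 'valid' convolution on (N, C, L) inputs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, init_scale: float = 1.0):
        scale = init_scale / np.sqrt(c_in * kernel)
        self.weight = Tensor(rng.normal(0.0, 1.0, (c_out, c_in, kernel)) * scale, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, padding=self.padding)


class GroupNorm(Module):
    """Group normalization over (N, C, L): statistics per (sample, group)."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, length = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * length)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xn = (xg - mu) / ((var + self.eps) ** 0.5)
        xn = xn.reshape(n, c, length)
        return xn * self.gamma.reshape(1, c, 1) + self.beta.reshape(1, c, 1)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return silu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    """Adam with the usual bias correction; operates on Tensor leaves in place."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
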