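"""Minimal reverse-mode automatic differentiation over numpy arrays.

The models in this package are small 1-D networks trained on CPU; this module
provides exactly the tensor operations they need (dense/convolutional layers,
pointwise nonlinearities, reductions, shifts and reshapes) with a taped
reverse pass.  All arithmetic is float64 throughout, which is what the exact
conservation and inversion contracts elsewhere in the package assume.

Only the forward values are stored on the tape; gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` in reverse topological order.
Broadcasting follows numpy semantics; the reverse pass sums gradients over
broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "pad1d",
    "roll",
    "conv1d",
    "avg_pool1d",
    "upsample_nearest1d",
    "softmax",
    "softplus",
    "sigmoid",
    "silu",
    "relu",
    "clip",
    "no_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # defer mixed numpy/Tensor arithmetic to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad or _parents else ()
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            # emit after children: use two-phase push
            stack_children = [p for p in node._parents if p.requires_grad and id(p) not in seen]
            if stack_children:
                stack.append(node)
                seen.discard(id(node))
                stack.extend(stack_children)
            else:
                topo.append(node)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        if not (self.requires_grad or other.requires_grad):
            return Tensor(out_data)

        def bw(g):
            return (
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            )

        return Tensor(out_data, True, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        if not self.requires_grad:
            return Tensor(-self.data)
        return Tensor(-self.data, True, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        if not (self.requires_grad or other.requires_grad):
            return Tensor(out_data)

        def bw(g):
            return (
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            )

        return Tensor(out_data, True, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data
        if not (self.requires_grad or other.requires_grad):
            return Tensor(out_data)

        def bw(g):
            return (
                (self, _unbroadcast(g / other.data, self.data.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)),
            )

        return Tensor(out_data, True, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p
        if not self.requires_grad:
            return Tensor(out_data)

        def bw(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor(out_data, True, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out_data = self.data @ other.data
        if not (self.requires_grad or other.requires_grad):
            return Tensor(out_data)

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (
                (self, _unbroadcast(ga, a.shape)),
                (other, _unbroadcast(gb, b.shape)),
            )

        return Tensor(out_data, True, (self, other), bw)

    # -- reductions & reshapes -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor(out_data, True, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not self.requires_grad:
            return Tensor(out_data)
        src = self.data.shape
        return Tensor(out_data, True, (self,), lambda g: ((self, g.reshape(src)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        out_data = self.data.transpose(axes)
        if not self.requires_grad:
            return Tensor(out_data)
        inv = tuple(np.argsort(axes))
        return Tensor(out_data, True, (self,), lambda g: ((self, g.transpose(inv)),))

    def __getitem__(self, idx):
        out_data = self.data[idx]
        if not self.requires_grad:
            return Tensor(out_data)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(out_data, True, (self,), bw)

    # -- pointwise nonlinearities ----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        out_data = np.log(self.data)
        if not self.requires_grad:
            return Tensor(out_data)
        return Tensor(out_data, True, (self,), lambda g: ((self, g / self.data),))

    def sqrt(self):
        return self**0.5


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- free functions -------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor(out_data, True, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, p.reshape(t.data.shape)) for t, p in zip(tensors, parts))

    return Tensor(out_data, True, tuple(tensors), bw)


def pad1d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the last axis by ``pad`` on both sides."""
    x = as_tensor(x)
    width = [(0, 0)] * (x.ndim - 1) + [(pad, pad)]
    out_data = np.pad(x.data, width)
    if not x.requires_grad:
        return Tensor(out_data)
    sl = (Ellipsis, slice(pad, out_data.shape[-1] - pad))
    return Tensor(out_data, True, (x,), lambda g: ((x, g[sl]),))


def roll(x: Tensor, shift: int, axis: int = -1) -> Tensor:
    """Circular shift along ``axis`` (periodic boundary)."""
    x = as_tensor(x)
    out_data = np.roll(x.data, shift, axis=axis)
    if not x.requires_grad:
        return Tensor(out_data)
    return Tensor(out_data, True, (x,), lambda g: ((x, np.roll(g, -shift, axis=axis)),))


def softplus(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable: log1p(exp(-|x|)) + max(x, 0)
    out_data = np.log1p(np.exp(-np.abs(x.data))) + np.maximum(x.data, 0.0)
    if not x.requires_grad:
        return Tensor(out_data)
    sig = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out_data, True, (x,), lambda g: ((x, g * sig),))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    if not x.requires_grad:
        return Tensor(out_data)
    return Tensor(out_data, True, (x,), lambda g: ((x, g * out_data * (1 - out_data)),))


def silu(x: Tensor) -> Tensor:
    return x * sigmoid(x)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.maximum(x.data, 0.0)
    if not x.requires_grad:
        return Tensor(out_data)
    mask = (x.data > 0).astype(np.float64)
    return Tensor(out_data, True, (x,), lambda g: ((x, g * mask),))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    x = as_tensor(x)
    out_data = np.clip(x.data, lo, hi)
    if not x.requires_grad:
        return Tensor(out_data)
    mask = ((x.data >= lo) & (x.data <= hi)).astype(np.float64)
    return Tensor(out_data, True, (x,), lambda g: ((x, g * mask),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stochastic softmax; the max-shift is detached (does not change grads)."""
    x = as_tensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """1-D cross-correlation: x (N, C_in, L), w (C_out, C_in, k), stride 1."""
    x, w = as_tensor(x), as_tensor(w)
    k = w.data.shape[-1]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N, C_in, L_out, k)
    out_data = np.einsum("nclk,ock->nol", cols, w.data, optimize=True)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[:, None]
    needs = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    if not needs:
        return Tensor(out_data)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        out = []
        if w.requires_grad:
            gw = np.einsum("nclk,nol->ock", cols, g, optimize=True)
            out.append((w, gw))
        if x.requires_grad:
            dcols = np.einsum("nol,ock->nclk", g, w.data, optimize=True)
            gxp = np.zeros_like(xp)
            L_out = g.shape[-1]
            for j in range(k):
                gxp[:, :, j : j + L_out] += dcols[:, :, :, j]
            gx = gxp[:, :, padding : gxp.shape[-1] - padding] if padding else gxp
            out.append((x, gx))
        if b is not None and b.requires_grad:
            out.append((b, g.sum(axis=(0, 2))))
        return tuple(out)

    return Tensor(out_data, True, parents, bw)


def avg_pool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping average pooling over the last axis (length must divide)."""
    x = as_tensor(x)
    L = x.data.shape[-1]
    if L % kernel:
        raise ValueError(f"length {L} not divisible by pool kernel {kernel}")
    new_shape = x.data.shape[:-1] + (L // kernel, kernel)
    out_data = x.data.reshape(new_shape).mean(axis=-1)
    if not x.requires_grad:
        return Tensor(out_data)

    def bw(g):
        gx = np.repeat(g, kernel, axis=-1) / kernel
        return ((x, gx),)

    return Tensor(out_data, True, (x,), bw)


def upsample_nearest1d(x: Tensor, factor: int) -> Tensor:
    x = as_tensor(x)
    out_data = np.repeat(x.data, factor, axis=-1)
    if not x.requires_grad:
        return Tensor(out_data)

    def bw(g):
        new_shape = g.shape[:-1] + (g.shape[-1] // factor, factor)
        return ((x, g.reshape(new_shape).sum(axis=-1)),)

    return Tensor(out_data, True, (x,), bw)
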