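"""Minimal reverse-mode automatic differentiation on numpy arrays.

The flow models in this package need gradients of exact log-likelihoods
through coupling layers, convolutional conditioners and alignment losses.
This module provides just enough machinery for that: a :class:`Tensor`
wrapping a float64 ndarray with a recorded backward closure, a small set of
differentiable operations (elementwise arithmetic, matmul, reductions,
reshaping, slicing, concatenation, and same-padded stride-1 N-D
convolution), a :class:`Module` container, and the Adamax optimizer with
global-norm gradient clipping and parameter EMA.

Everything is double precision and single-device; the engine favours
correctness and debuggability over speed, which is adequate for the
desk-scale models this package trains.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "stack_rows",
    "logsumexp",
    "conv_nd",
    "Module",
    "Linear",
    "MLP",
    "ConvNd",
    "Adamax",
    "EMA",
    "clip_global_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- shape ----------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data**p

        def backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- elementwise nonlinearities --------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out_data**2))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(np.where(mask, self.data, 0.0), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * 0.5 / out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def abs(self):
        sign = np.sign(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * sign)

        out = Tensor._make(np.abs(self.data), (self,), backward)
        return out

    # -- reductions & shaping ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out = Tensor._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    @property
    def T(self):
        return self.transpose(tuple(reversed(range(self.ndim))))

    def __getitem__(self, idx):
        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out = Tensor._make(self.data[idx], (self,), backward)
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- backprop ----------------------------------------------------------------

    def backward(self) -> None:
        """Run reverse-mode accumulation from this (scalar or any-shape) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def Parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack same-shape tensors along a new leading axis."""
    out_data = np.stack([t.data for t in tensors])

    def backward():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(out.grad[i])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along one axis."""
    m = np.max(x.data, axis=axis, keepdims=True)  # constant shift
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != (axis % x.ndim)))
    return out


# ---------------------------------------------------------------------------
# N-D convolution (same padding, stride 1), the workhorse of Glow conditioners
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, ksizes: tuple[int, ...]) -> np.ndarray:
    """(B, C, *spatial) -> (B, prod(spatial), C*prod(k)) with same padding."""
    nd = len(ksizes)
    pads = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in ksizes]
    xp = np.pad(x, pads)
    win = np.lib.stride_tricks.sliding_window_view(
        xp, ksizes, axis=tuple(range(2, 2 + nd))
    )
    # win: (B, C, *spatial, *k)
    B, C = x.shape[:2]
    spatial = x.shape[2:]
    order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    cols = win.transpose(order).reshape(B, int(np.prod(spatial)), C * int(np.prod(ksizes)))
    return np.ascontiguousarray(cols)


def _col2im(grad_cols: np.ndarray, x_shape: tuple[int, ...], ksizes: tuple[int, ...]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    nd = len(ksizes)
    B, C = x_shape[:2]
    spatial = x_shape[2:]
    padded = tuple(s + 2 * (k // 2) for s, k in zip(spatial, ksizes))
    gxp = np.zeros((B, C) + padded)
    gc = grad_cols.reshape((B,) + tuple(spatial) + (C,) + tuple(ksizes))
    # move C before spatial: (B, C, *spatial, *k)
    order = (0, 1 + nd) + tuple(range(1, 1 + nd)) + tuple(range(2 + nd, 2 + 2 * nd))
    gc = gc.transpose(order)
    for offset in np.ndindex(*ksizes):
        sl = tuple(slice(o, o + s) for o, s in zip(offset, spatial))
        gxp[(slice(None), slice(None)) + sl] += gc[
            (slice(None), slice(None)) + tuple(slice(None) for _ in spatial) + offset
        ]
    crop = tuple(slice(k // 2, k // 2 + s) for s, k in zip(spatial, ksizes))
    return gxp[(slice(None), slice(None)) + crop]


def conv_nd(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded stride-1 convolution for 1/2/3 spatial dimensions.

    x: (B, Cin, *spatial); weight: (Cout, Cin, *k); bias: (Cout,).
    """
    ksizes = weight.shape[2:]
    B = x.shape[0]
    spatial = x.shape[2:]
    cout = weight.shape[0]
    cols = _im2col(x.data, ksizes)  # (B, P, Cin*K)
    w2 = weight.data.reshape(cout, -1)
    out2 = cols @ w2.T + bias.data  # (B, P, Cout)
    out_data = np.moveaxis(out2, -1, 1).reshape((B, cout) + tuple(spatial))

    def backward():
        go2 = np.moveaxis(out.grad.reshape(B, cout, -1), 1, -1)  # (B, P, Cout)
        if weight.requires_grad:
            gw = np.einsum("bpo,bpk->ok", go2, cols).reshape(weight.data.shape)
            weight._accum(gw)
        if bias.requires_grad:
            bias._accum(go2.sum(axis=(0, 1)))
        if x.requires_grad:
            grad_cols = go2 @ w2  # (B, P, Cin*K)
            x._accum(_col2im(grad_cols, x.data.shape, ksizes))

    out = Tensor._make(out_data, (x, weight, bias), backward)
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Lightweight parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((out_dim, in_dim))
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(out_dim, in_dim))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.T + self.bias


class MLP(Module):
    """Tanh MLP; optional zero-initialized final layer (identity-start couplings)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator,
                 zero_init_last: bool = False):
        self.layers = [
            Linear(dims[i], dims[i + 1], rng,
                   zero_init=(zero_init_last and i == len(dims) - 2))
            for i in range(len(dims) - 1)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).tanh()
        return self.layers[-1](x)


class ConvNd(Module):
    def __init__(self, in_ch: int, out_ch: int, ksize: int, nd: int,
                 rng: np.random.Generator, zero_init: bool = False):
        shape = (out_ch, in_ch) + (ksize,) * nd
        fan_in = in_ch * ksize**nd
        if zero_init:
            w = np.zeros(shape)
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


class Adamax(Module):
    """Adamax (Adam with infinity-norm second moment)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._u = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bias_corr = 1.0 - b1**self.t
        for p, m, u in zip(self.params, self._m, self._u):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            np.maximum(b2 * u, np.abs(p.grad), out=u)
            p.data -= (self.lr / bias_corr) * m / (u + self.eps)


def clip_global_norm(params: Sequence[Tensor], max_norm: float) -> float:
    """Scale gradients so the global L2 norm is at most `max_norm`; returns the pre-clip norm."""
    sq = 0.0
    for p in params:
        if p.grad is not None:
            sq += float(np.sum(p.grad**2))
    norm = float(np.sqrt(sq))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class EMA:
    """Exponential moving average of a parameter list: ema <- d*ema + (1-d)*p."""

    def __init__(self, params: Sequence[Tensor], decay: float = 0.999):
        if not (0.0 <= decay < 1.0):
            raise ValueError("EMA decay must lie in [0, 1)")
        self.decay = float(decay)
        self.params = list(params)
        self.shadow = [p.data.copy() for p in self.params]

    def update(self) -> None:
        d = self.decay
        for s, p in zip(self.shadow, self.params):
            if s.shape != p.data.shape:
                raise ValueError("EMA shape mismatch")
            s *= d
            s += (1 - d) * p.data

    def copy_to(self, params: Sequence[Tensor]) -> None:
        for s, p in zip(self.shadow, params):
            p.data = s.copy()
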