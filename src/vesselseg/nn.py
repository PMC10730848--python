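"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module is the numerical substrate for the segmentation network: a
tape-based :class:`Tensor`, the handful of differentiable operations the
architecture needs (3x3/1x1 convolution via im2col + BLAS, 2x2 stride-2
transposed convolution, batch normalisation, 2x2 max pooling with argmax
indices and the matching unpooling, Haar analysis/synthesis, channel
concatenation, softmax, ReLU, elementwise arithmetic and reductions),
:class:`Module` parameter management, and the Adam optimiser.

Every backward pass is written by hand and checked against central finite
differences in the test suite.  All arithmetic is float64; determinism is
inherited from NumPy (no threading of our own, seeded initialisation).
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Sequence

import numpy as np
from . import wavelet as _wv

DTYPE = np.float64

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode; saves memory)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the tape bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    # -- public surface -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go: closures may pin large buffers
                node._backward = None
                node._parents = ()

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def sum(self):
        def bw(g):
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(), (self,), bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accum(np.broadcast_to(g / n, self.data.shape))

        return Tensor._make(self.data.mean(), (self,), bw)

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def log(x: Tensor, clamp: float = 0.0) -> Tensor:
    """Natural log; values are clamped below at `clamp` (zero gradient there)."""
    clamped = np.maximum(x.data, clamp) if clamp else x.data
    active = x.data >= clamp

    def bw(g):
        x._accum(g * active / clamped)

    return Tensor._make(np.log(clamped), (x,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        offs = np.cumsum([0] + sizes)
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad or t._parents:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), bw)


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C*k*k, H*W) patch matrix for stride-1 windows.

    Assembled by k*k shifted slice copies (fast, cache-friendly) rather
    than a gather over sliding windows.
    """
    n, c, hp, wp = xp.shape
    h, w = hp - k + 1, wp - k + 1
    out = np.empty((n, c, k * k, h, w), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i * k + j] = xp[:, :, i : i + h, j : j + w]
    return out.reshape(n, c * k * k, h * w)


def _conv_forward(x: np.ndarray, w: np.ndarray, pad: int):
    n, c, h, ww = x.shape
    o, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = _im2col(xp, k)
    y = np.matmul(w.reshape(o, -1), cols).reshape(n, o, h, ww)
    return y, cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """Stride-1 'same' cross-correlation: kernel k, padding (k-1)/2."""
    n, c, h, ww = x.data.shape
    o, ci, k, _ = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    y, cols = _conv_forward(x.data, w.data, pad)
    if b is not None:
        y += b.data.reshape(1, o, 1, 1)
    if not _grad_enabled:
        return Tensor(y)

    def bw(g):
        gf = g.reshape(n, o, -1)
        if w.requires_grad or w._parents:
            dw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            wt = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            dx, _ = _conv_forward(g, wt, k - 1 - pad)
            x._accum(dx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x2, stride-2 transposed convolution (exact 2x upsampling, no overlap).

    Weight layout is (C_in, C_out, 2, 2).
    """
    n, c, h, ww = x.data.shape
    ci, o, _, _ = w.data.shape
    if ci != c:
        raise ValueError(f"conv_transpose2x2: input has {c} channels, weight expects {ci}")
    # y[n,o,2h+i,2w+j] = sum_c x[n,c,h,w] * W[c,o,i,j]  (no window overlap)
    xf = x.data.transpose(0, 2, 3, 1).reshape(-1, c)  # (N*H*W, C)
    wf = w.data.reshape(c, o * 4)
    y6 = (xf @ wf).reshape(n, h, ww, o, 2, 2)
    y = np.ascontiguousarray(y6.transpose(0, 3, 1, 4, 2, 5)).reshape(n, o, 2 * h, 2 * ww)
    if b is not None:
        y += b.data.reshape(1, o, 1, 1)
    if not _grad_enabled:
        return Tensor(y)

    def bw(g):
        g6 = g.reshape(n, o, h, 2, ww, 2)
        gf = np.ascontiguousarray(g6.transpose(0, 2, 4, 1, 3, 5)).reshape(-1, o * 4)
        if x.requires_grad or x._parents:
            dx = (gf @ wf.T).reshape(n, h, ww, c).transpose(0, 3, 1, 2)
            x._accum(dx)
        if w.requires_grad or w._parents:
            w._accum((xf.T @ gf).reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, bw)


def max_pool2x2(x: Tensor) -> tuple[Tensor, np.ndarray]:
    """2x2 stride-2 max pool.

    Returns the pooled tensor and an integer index array of the pooled shape
    whose values are the row-major position (0..3 = TL,TR,BL,BR) of the
    retained maximum inside its window; ties keep the first position.
    """
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2: spatial dims ({h},{w}) must be even")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        z = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(z, idx[..., None], g[..., None], axis=-1)
        x._accum(
            z.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    return Tensor._make(y, (x,), bw), idx


def max_unpool2x2(x: Tensor, idx: np.ndarray, out_size: tuple[int, int] | None = None) -> Tensor:
    """Place each pooled value at its recorded window position, zeros elsewhere."""
    n, c, h2, w2 = x.data.shape
    if idx.shape != x.data.shape:
        raise ValueError(f"index shape {idx.shape} != input shape {x.data.shape}")
    if idx.min() < 0 or idx.max() > 3:
        raise ValueError("pool indices must lie inside their own 2x2 window (0..3)")
    h, w = out_size if out_size is not None else (2 * h2, 2 * w2)
    if (h, w) != (2 * h2, 2 * w2):
        raise ValueError(f"output size {(h, w)} incompatible with pooled size {(h2, w2)}")
    z = np.zeros((n, c, h2, w2, 4), dtype=DTYPE)
    np.put_along_axis(z, idx[..., None], x.data[..., None], axis=-1)
    y = z.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)

    def bw(g):
        gv = g.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        x._accum(np.take_along_axis(gv, idx[..., None], axis=-1)[..., 0])

    return Tensor._make(y, (x,), bw)


def haar_down(x: Tensor) -> Tensor:
    """Differentiable grouped Haar analysis: (N,C,H,W) -> (N,4C,H/2,W/2).

    The transform is orthonormal, so the vector-Jacobian product is the
    synthesis transform of the incoming gradient.
    """
    y = _wv.dwt_concat(x.data)

    def bw(g):
        x._accum(_wv.split_idwt(g))

    return Tensor._make(y, (x,), bw)


def haar_up(x: Tensor) -> Tensor:
    """Differentiable grouped Haar synthesis: (N,4C,H,W) -> (N,C,2H,2W)."""
    y = _wv.split_idwt(x.data)

    def bw(g):
        x._accum(_wv.dwt_concat(g))

    return Tensor._make(y, (x,), bw)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an (N,C,H,W) tensor."""
    m = x.data.max(axis=1, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=1, keepdims=True)

    def bw(g):
        x._accum(y * (g - (g * y).sum(axis=1, keepdims=True)))

    return Tensor._make(y, (x,), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterable[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {name: p.data for name, p in self.named_parameters(prefix)}
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray) and name.startswith("running_"):
                out[prefix + name] = val
        for name, child in self._children():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, val in list(vars(self).items()):
            key = prefix + name
            if isinstance(val, Parameter):
                val.data = np.array(state[key], dtype=DTYPE)
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                setattr(self, name, np.array(state[key], dtype=DTYPE))
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")


class Conv2d(Module):
    """Stride-1 'same' convolution with He-normal initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("only odd kernels supported (size-preserving)")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        fan_in = in_channels * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.data.shape[1]}"
            )
        return conv2d(x, self.weight, self.bias, self.pad)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        std = math.sqrt(2.0 / (in_channels * 4))
        self.weight = Parameter(rng.normal(0.0, std, (in_channels, out_channels, 2, 2)))
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Normalisation uses biased batch variance; running variance tracks the
    unbiased estimate (standard framework behaviour). momentum=0.1, eps=1e-5.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        sh = (1, self.channels, 1, 1)
        if self.training:
            axes = (0, 2, 3)
            m = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            cnt = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * cnt / max(cnt - 1, 1)
            self.running_mean += self.momentum * (m - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            ivstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - m.reshape(sh)) * ivstd.reshape(sh)
            y = self.gamma.data.reshape(sh) * xhat + self.beta.data.reshape(sh)
            gamma, beta = self.gamma, self.beta

            def bw(g):
                if gamma.requires_grad:
                    gamma._accum((g * xhat).sum(axis=axes))
                if beta.requires_grad:
                    beta._accum(g.sum(axis=axes))
                if x.requires_grad or x._parents:
                    gh = g * gamma.data.reshape(sh)
                    iv = ivstd.reshape(sh)
                    t1 = gh.sum(axis=axes, keepdims=True)
                    t2 = (gh * xhat).sum(axis=axes, keepdims=True)
                    x._accum(iv * (gh - t1 / cnt - xhat * t2 / cnt))

            return Tensor._make(y, (x, gamma, beta), bw)
        # inference: affine transform with frozen statistics
        ivstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x.data - self.running_mean.reshape(sh)) * ivstd.reshape(sh)
        y = self.gamma.data.reshape(sh) * xhat + self.beta.data.reshape(sh)
        gamma, beta = self.gamma, self.beta

        def bw_eval(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                x._accum(g * (gamma.data * ivstd).reshape(sh))

        return Tensor._make(y, (x, gamma, beta), bw_eval)


class Adam:
    """Adam with the standard bias correction (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
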