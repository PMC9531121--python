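"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine supports exactly the operations the tongue-quality networks need:
dense and 3x3/1x1 convolutional layers, 2x2 max-pooling, bilinear 2x
upsampling, channel concatenation, ReLU, channel dropout, softmax, and the
elementwise/reduction arithmetic used by the loss functions.  Everything is
float32 and deterministic: randomness (init, dropout) is injected through
explicit ``numpy.random.Generator`` objects.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample_bilinear2x",
    "dropout_channels",
    "softmax",
    "relu",
    "softplus",
    "stack_rows",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation / Monte-Carlo passes)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[-1]
        self._backward: Optional[Callable[[], None]] = None
        self._parents: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward():
            self._accumulate(-out.grad)

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -out.grad * self.data / (other.data ** 2), other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,), None)

        def backward():
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward if out.requires_grad else None
        return out

    def __getitem__(self, key):
        out = self._make(self.data[key], (self,), None)

        def backward():
            g = np.zeros_like(self.data)
            np.add.at(g, key, out.grad)
            self._accumulate(g)

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = backward if out.requires_grad else None
        return out

    # -- unary / reductions -----------------------------------------------
    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward():
            self._accumulate(out.grad / self.data)

        out._backward = backward if out.requires_grad else None
        return out

    def exp(self):
        out = self._make(np.exp(self.data), (self,), None)

        def backward():
            self._accumulate(out.grad * out.data)

        out._backward = backward if out.requires_grad else None
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior only."""
        out = self._make(np.clip(self.data, lo, hi), (self,), None)

        def backward():
            inside = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)
            self._accumulate(out.grad * inside)

        out._backward = backward if out.requires_grad else None
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def backward():
            self._accumulate(out.grad.reshape(self.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def permute(self, *axes):
        inv = np.argsort(axes)
        out = self._make(np.ascontiguousarray(self.data.transpose(axes)),
                         (self,), None)

        def backward():
            self._accumulate(np.ascontiguousarray(out.grad.transpose(inv)))

        out._backward = backward if out.requires_grad else None
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- non-method operations ------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = x._make(np.maximum(x.data, 0.0), (x,), None)

    def backward():
        x._accumulate(out.grad * (x.data > 0))

    out._backward = backward if out.requires_grad else None
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable; d/dx = sigmoid(x)."""
    data = np.logaddexp(0.0, x.data).astype(np.float32)
    out = x._make(data, (x,), None)

    def backward():
        sig = 1.0 / (1.0 + np.exp(-x.data))
        x._accumulate(out.grad * sig.astype(np.float32))

    out._backward = backward if out.requires_grad else None
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = x._make(y.astype(np.float32), (x,), None)

    def backward():
        g = out.grad
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate((y * (g - dot)).astype(np.float32))

    out._backward = backward if out.requires_grad else None
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    out = Tensor(out_data)
    parents = tuple(t for t in tensors if t.requires_grad)
    if _GRAD_ENABLED[-1] and parents:
        out.requires_grad = True
        out._parents = parents
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out_data.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(sl)])

        out._backward = backward
    return out


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack scalar/1-D tensors into one vector (used for sigma pairs)."""
    out_data = np.stack([np.atleast_1d(t.data).reshape(()) for t in tensors])
    out = Tensor(out_data)
    parents = tuple(t for t in tensors if t.requires_grad)
    if _GRAD_ENABLED[-1] and parents:
        out.requires_grad = True
        out._parents = parents

        def backward():
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accumulate(out.grad[i].reshape(t.shape))

        out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor], pad: int) -> Tensor:
    """Same-size 2-D convolution (stride 1), channels-last activations.

    x: (B, H, W, C); weight: (Co, C, k, k); bias: (Co,) or None.
    Computed as one GEMM against all k*k kernel taps on the padded input
    followed by shifted slice-sums, which keeps every matrix product on
    contiguous memory (much faster than im2col gathers on one CPU core).
    """
    B, H, W, C = x.shape
    Co, Ci, k, _ = weight.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    if pad:
        xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    else:
        xp = x.data
    Hp, Wp = xp.shape[1], xp.shape[2]
    Ho, Wo = Hp - k + 1, Wp - k + 1
    wmats = np.ascontiguousarray(weight.data.transpose(2, 3, 1, 0))  # k,k,C,Co
    # P[b,u,v,i,j,co] = xp[b,u,v,:] @ W[i,j,:,:]
    p_all = (xp.reshape(B * Hp * Wp, C) @
             np.ascontiguousarray(wmats.transpose(2, 0, 1, 3)).reshape(C, k * k * Co))
    p_all = p_all.reshape(B, Hp, Wp, k, k, Co)
    out_data = np.zeros((B, Ho, Wo, Co), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out_data += p_all[:, i:i + Ho, j:j + Wo, i, j, :]
    if bias is not None:
        out_data += bias.data
    out = Tensor(out_data)
    parents = tuple(t for t in (x, weight, bias) if t is not None and t.requires_grad)
    if _GRAD_ENABLED[-1] and parents:
        out.requires_grad = True
        out._parents = parents

        def backward():
            g = out.grad                                    # B,Ho,Wo,Co
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1, 2)))
            if weight.requires_grad:
                gp = np.zeros((B, Hp, Wp, k, k, Co), dtype=np.float32)
                for i in range(k):
                    for j in range(k):
                        gp[:, i:i + Ho, j:j + Wo, i, j, :] = g
                dwall = xp.reshape(B * Hp * Wp, C).T @ \
                    gp.reshape(B * Hp * Wp, k * k * Co)
                dw = dwall.reshape(C, k, k, Co).transpose(3, 0, 1, 2)
                weight._accumulate(np.ascontiguousarray(dw))
            if x.requires_grad:
                # dxp[b,u,v,c] = sum_{i,j} g[b,u-i,v-j,co] W[i,j,c,co]
                wback = np.ascontiguousarray(
                    wmats.transpose(3, 0, 1, 2)).reshape(Co, k * k * C)
                dp = (g.reshape(B * Ho * Wo, Co) @ wback)
                dp = dp.reshape(B, Ho, Wo, k, k, C)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, i:i + Ho, j:j + Wo, :] += dp[:, :, :, i, j, :]
                if pad:
                    dxp = dxp[:, pad:-pad, pad:-pad, :]
                x._accumulate(np.ascontiguousarray(dxp))

        out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, channels-last (B, H, W, C)."""
    B, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    Ho, Wo = H // 2, W // 2
    x4 = x.data.reshape(B, Ho, 2, Wo, 2, C).transpose(0, 1, 3, 2, 4, 5)
    x4 = np.ascontiguousarray(x4).reshape(B, Ho, Wo, 4, C)
    idx = x4.argmax(axis=3)
    out = Tensor(np.take_along_axis(x4, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :])
    if _GRAD_ENABLED[-1] and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward():
            g4 = np.zeros_like(x4)
            np.put_along_axis(g4, idx[:, :, :, None, :], out.grad[:, :, :, None, :],
                              axis=3)
            g = g4.reshape(B, Ho, Wo, 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
            x._accumulate(np.ascontiguousarray(g).reshape(B, H, W, C))

        out._backward = backward
    return out


_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(n: int) -> np.ndarray:
    """(2n x n) linear-interpolation matrix, half-pixel centers."""
    m = _BILINEAR_CACHE.get(n)
    if m is None:
        m = np.zeros((2 * n, n), dtype=np.float32)
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            lo = int(np.floor(src))
            w = src - lo
            lo_c = min(max(lo, 0), n - 1)
            hi_c = min(max(lo + 1, 0), n - 1)
            m[o, lo_c] += 1.0 - w
            m[o, hi_c] += w
        _BILINEAR_CACHE[n] = m
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x upsampling (half-pixel centers), channels-last.

    Separable: rows then columns, each a broadcast matmul with a fixed
    interpolation matrix, so the gradient is exactly the transpose map.
    """
    B, H, W, C = x.shape
    mr, mc = _bilinear_matrix(H), _bilinear_matrix(W)
    t = np.matmul(mr, x.data.reshape(B, H, W * C))       # B,2H,W*C
    t = t.reshape(B * 2 * H, W, C)
    y = np.matmul(mc, t).reshape(B, 2 * H, 2 * W, C)
    out = Tensor(y)
    if _GRAD_ENABLED[-1] and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward():
            g = out.grad.reshape(B * 2 * H, 2 * W, C)
            t2 = np.matmul(mc.T, g).reshape(B, 2 * H, W * C)
            gx = np.matmul(mr.T, t2).reshape(B, H, W, C)
            x._accumulate(gx)

        out._backward = backward
    return out


def dropout_channels(x: Tensor, rate: float, rng: np.random.Generator,
                     active: bool) -> Tensor:
    """2-D (channel-wise) dropout with inverted scaling, channels-last.

    When ``active`` is False this is the identity (evaluation mode)."""
    if not active or rate <= 0.0:
        return x
    B, C = x.shape[0], x.shape[-1]
    keep = (rng.random((B, 1, 1, C)) >= rate).astype(np.float32) / (1.0 - rate)
    return x * Tensor(keep)
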