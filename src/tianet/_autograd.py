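"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional networks on CPU; this module provides
exactly the operations those networks need — dense/conv linear maps, ReLU,
sigmoid, max-pooling, softmax cross-entropy, elementwise arithmetic with
broadcasting — as a :class:`Tensor` graph with a topological-sort backward
pass, plus an SGD-with-momentum optimizer.  All randomness (dropout masks,
initialisation) is injected by callers through explicit ``numpy`` generators;
nothing here touches global RNG state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "SGD", "cross_entropy", "dropout", "conv2d", "maxpool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in a dynamically built computation graph.

    Only leaf tensors created with ``requires_grad=True`` accumulate
    gradients callers can read; interior nodes are garbage-collected with
    the graph.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from long training loops are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # break the node <-> closure reference cycles so the graph (and the
        # large activation buffers it holds) is freed by refcount immediately
        for node in topo:
            node._backward = None
            node._prev = ()
            if node is not self and node.grad is not None and not node.requires_grad:
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data)
        out._prev = (self, other)

        def _bw():
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._prev = (self,)
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data)
        out._prev = (self, other)

        def _bw():
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent)
        out._prev = (self,)

        def _bw():
            self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = _bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data)
        out._prev = (self, other)

        def _bw():
            a, b = self.data, other.data
            ga = out.grad @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ out.grad
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape))
        out._prev = (self,)
        out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes))
        out._prev = (self,)
        inv = np.argsort(axes)
        out._backward = lambda: self._accum(out.grad.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._prev = (self,)

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0))
        out._prev = (self,)
        out._backward = lambda: self._accum(out.grad * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic, split by sign to avoid overflow
        s = np.empty_like(self.data)
        pos = self.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        s[~pos] = e / (1.0 + e)
        out = Tensor(s)
        out._prev = (self,)
        out._backward = lambda: self._accum(out.grad * s * (1.0 - s))
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data))
        out._prev = (self,)
        out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data))
        out._prev = (self,)
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'None'})"


# ---------------------------------------------------------------------------
# Convolution / pooling
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (C*kh*kw, N*oh*ow) patch matrix, stride 1."""
    n, c, hp, wp = xp.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (N, C, oh, ow, kh, kw) -> (C, kh, kw, N, oh, ow); one contiguous copy
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * kh * kw, n * oh * ow)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, symmetric zero padding.

    x: (N,C,H,W); w: (F,C,kh,kw); b: (F,). Returns (N,F,oh,ow).
    Implemented as one im2col GEMM per call so BLAS does the heavy lifting.
    """
    n, c, h, wid = x.shape
    f, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw)  # (K, N*L)
    w2d = w.data.reshape(f, -1)
    oh, ow = h + 2 * padding - kh + 1, wid + 2 * padding - kw + 1
    out2 = w2d @ cols  # (F, N*L)
    out2 += b.data[:, None]
    out_data = out2.reshape(f, n, oh * ow).transpose(1, 0, 2).reshape(n, f, oh, ow)
    out = Tensor(np.ascontiguousarray(out_data))
    out._prev = (x, w, b)

    def _bw():
        dout2 = np.ascontiguousarray(
            out.grad.reshape(n, f, -1).transpose(1, 0, 2)
        ).reshape(f, -1)  # (F, N*L)
        b._accum(dout2.sum(axis=1))
        w._accum((dout2 @ cols.T).reshape(w.shape))
        dcols = (w2d.T @ dout2).reshape(c, kh, kw, n, oh, ow)
        dxp = np.zeros_like(xp)
        dxp_t = dxp.transpose(1, 0, 2, 3)  # (C,N,Hp,Wp) view
        for i in range(kh):
            for j in range(kw):
                dxp_t[:, :, i : i + oh, j : j + ow] += dcols[:, i, j]
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    out._backward = _bw
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k max pooling; spatial dims must be divisible by k."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial dims ({h},{w}) not divisible by {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    out_data = xr.max(axis=(3, 5))
    out = Tensor(out_data)
    out._prev = (x,)

    def _bw():
        mask = xr == out_data[:, :, :, None, :, None]
        # split gradient evenly among tied maxima so backward stays deterministic
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = (out.grad[:, :, :, None, :, None] / counts) * mask
        x._accum(g.reshape(n, c, h, w))

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# Losses / regularisation helpers
# ---------------------------------------------------------------------------


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-softmax of the true class.  logits: (B,K)."""
    labels = np.asarray(labels)
    b, k = logits.shape
    if labels.shape != (b,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {b}")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels out of range [0,{k})")
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss_val = -logp[np.arange(b), labels].mean()
    out = Tensor(np.asarray(loss_val, dtype=z.dtype))
    out._prev = (logits,)

    def _bw():
        softmax = np.exp(logp)
        g = softmax.copy()
        g[np.arange(b), labels] -= 1.0
        logits._accum(out.grad * g / b)

    out._backward = _bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(mask)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    Only the tensors handed to the constructor are ever updated — freezing a
    layer is done by excluding its parameters from the optimizer.
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(float((p.grad.astype(np.float64) ** 2).sum())
                     for p in self.params if p.grad is not None)
            norm = np.sqrt(sq)
            if not np.isfinite(norm):
                return  # skip the update rather than poison the weights
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
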