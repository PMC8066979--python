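"""Channel-wise attention: recalibrate transferred features G into P.

The attention head squeezes each channel of the feature map G to a scalar by
global average pooling (GAP), passes the descriptor o through a two-layer
bottleneck W1(W0 o), and applies a sigmoid to obtain per-channel gates
m in (0,1).  The specific feature is the channel-wise reweighting
P = G (x) m, with m broadcast over the spatial dimensions.

Two surfaces are provided:

* pure-numpy functions (``global_average_pool``, ``channel_attention``,
  ``reweight``) that implement the algebra exactly, used directly by oracle
  tests and by any caller that only needs the arithmetic;
* :class:`ChannelAttention`, the trainable module running the same algebra
  on the autodiff graph.

By default there is **no** nonlinearity between W0 and W1 — the composition
is the plain product sigmoid(W1 W0 o); an inner-ReLU variant (the
squeeze-excitation convention) is available behind a flag.  Biases on both
FC maps are included by default and can be disabled.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = [
    "global_average_pool",
    "channel_attention",
    "reweight",
    "ChannelAttention",
]


def global_average_pool(G: np.ndarray) -> np.ndarray:
    """Spatial mean per channel: o_c = (1/WH) sum_ij G_c(i,j).

    Accepts (C,H,W) or batched (N,C,H,W); returns (C,) or (N,C).
    """
    G = np.asarray(G)
    if G.ndim not in (3, 4):
        raise ValueError(f"expected (C,H,W) or (N,C,H,W), got shape {G.shape}")
    if G.shape[-1] == 0 or G.shape[-2] == 0:
        raise ValueError("feature map has empty spatial dimensions")
    return G.mean(axis=(-2, -1))


def channel_attention(
    o: np.ndarray,
    W0: np.ndarray,
    W1: np.ndarray,
    b0: np.ndarray | None = None,
    b1: np.ndarray | None = None,
    inner_relu: bool = False,
) -> np.ndarray:
    """Attention gates m = sigmoid(W1 (W0 o)).  W0: (r,C), W1: (C,r)."""
    o, W0, W1 = np.asarray(o), np.asarray(W0), np.asarray(W1)
    if W0.shape[1] != o.shape[-1]:
        raise ValueError(f"W0 columns {W0.shape[1]} != len(o) {o.shape[-1]}")
    if W1.shape[1] != W0.shape[0]:
        raise ValueError(f"W1 columns {W1.shape[1]} != W0 rows {W0.shape[0]}")
    h = o @ W0.T
    if b0 is not None:
        h = h + b0
    if inner_relu:
        h = np.maximum(h, 0.0)
    z = h @ W1.T
    if b1 is not None:
        z = z + b1
    with np.errstate(over="ignore"):
        m = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                     np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    # keep the gates strictly inside (0,1) even when the sigmoid saturates
    eps = 1e-300
    return np.clip(m, eps, 1.0 - 1e-16)


def reweight(G: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Specific feature P_c(i,j) = G_c(i,j) * m_c (broadcast over space)."""
    G, m = np.asarray(G), np.asarray(m)
    if G.shape[-3] != m.shape[-1]:
        raise ValueError(f"channel mismatch: G has {G.shape[-3]}, m has {m.shape[-1]}")
    return G * m[..., :, None, None]


class ChannelAttention:
    """Trainable channel-attention head on the autodiff graph."""

    def __init__(self, channels: int, seed: int, ratio: int = 4,
                 use_bias: bool = True, inner_relu: bool = False):
        r = max(channels // ratio, 4)
        rng = np.random.default_rng(seed)
        self.channels = channels
        self.inner_relu = inner_relu
        self.use_bias = use_bias
        self.W0 = Tensor(
            rng.normal(0, np.sqrt(2.0 / channels), (r, channels)).astype(np.float32),
            requires_grad=True,
        )
        self.W1 = Tensor(
            rng.normal(0, np.sqrt(2.0 / r), (channels, r)).astype(np.float32),
            requires_grad=True,
        )
        self.b0 = Tensor(np.zeros(r, dtype=np.float32), requires_grad=True)
        self.b1 = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def attention_vector(self, G: Tensor) -> Tensor:
        """Per-sample gates m: (N, C) for a feature map (N, C, H, W)."""
        n, c, h, w = G.shape
        o = G.reshape(n, c, h * w).mean(axis=2)
        z = o @ self.W0.transpose(1, 0)
        if self.use_bias:
            z = z + self.b0
        if self.inner_relu:
            z = z.relu()
        z = z @ self.W1.transpose(1, 0)
        if self.use_bias:
            z = z + self.b1
        return z.sigmoid()

    def __call__(self, G: Tensor) -> tuple[Tensor, Tensor]:
        """Return (P, m): the reweighted feature map and the gates."""
        m = self.attention_vector(G)
        n, c = m.shape
        P = G * m.reshape(n, c, 1, 1)
        return P, m

    def parameters(self) -> list[Tensor]:
        ps = [self.W0, self.W1]
        if self.use_bias:
            ps += [self.b0, self.b1]
        return ps
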