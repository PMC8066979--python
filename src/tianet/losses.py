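"""Transfer objective: source CE + target CE + lambda * MMD^2.

The discrepancy term is the squared Maximum Mean Discrepancy between the
per-sample attention vectors of the source and target minibatches,

    MMD^2(ms, mt) = || mean_i phi(ms_i) - mean_j phi(mt_j) ||^2_H,

estimated with the biased V-statistic, which expands to

    (1/Ns^2) sum k(s,s') + (1/Nt^2) sum k(t,t') - (2/(Ns Nt)) sum k(s,t).

The kernel is Gaussian RBF by default with a median-heuristic bandwidth over
the pooled pairwise distances of the current batch pair (the bandwidth is
treated as a constant of the step, not differentiated through); linear and
polynomial kernels are provided mainly so tests can compare against the
closed-form mean-embedding distance.  An unbiased U-statistic estimator is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor
from ._autograd import cross_entropy as _ce_graph

__all__ = ["LossConfig", "cross_entropy", "mmd_squared", "mmd_squared_graph",
           "combined_loss"]

_KERNELS = ("gaussian_rbf", "linear", "polynomial")


@dataclass(frozen=True)
class LossConfig:
    lambda_disc: float = 1.0
    kernel: str = "gaussian_rbf"
    bandwidth: float | str = "median-heuristic"
    poly_degree: int = 3
    unbiased: bool = False
    #: what the discrepancy is computed on: attention gates m, or GAP(G)
    #: when the attention head is ablated
    mmd_on: str = "attention"

    def __post_init__(self):
        if self.lambda_disc < 0:
            raise ValueError("lambda_disc must be non-negative")
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median-heuristic":
                raise ValueError("bandwidth must be positive or 'median-heuristic'")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.mmd_on not in ("attention", "gap"):
            raise ValueError("mmd_on must be 'attention' or 'gap'")


def cross_entropy(logits: np.ndarray | Tensor, labels: np.ndarray) -> float:
    """Mean negative log-softmax of the true class, as a plain float."""
    t = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits, dtype=float))
    return float(_ce_graph(t, labels).data)


#: lower bound on the median-heuristic sigma^2 — without it the RBF gradient
#: scales like 1/sigma^2 and explodes once the gate distributions collapse
_BANDWIDTH_FLOOR = 1e-3


def _median_sq_bandwidth(ms: np.ndarray, mt: np.ndarray) -> float:
    """sigma^2 = median of the pooled nonzero pairwise squared distances."""
    z = np.concatenate([ms, mt], axis=0)
    sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
    vals = sq[np.triu_indices_from(sq, k=1)]
    vals = vals[vals > 0]
    med = float(np.median(vals)) if vals.size else 1.0
    return max(med, _BANDWIDTH_FLOOR)


def _pairwise_sq_dists(x: Tensor, y: Tensor) -> Tensor:
    xx = (x * x).sum(axis=1, keepdims=True)  # (Nx,1)
    yy = (y * y).sum(axis=1, keepdims=True).reshape(1, -1)  # (1,Ny)
    return xx + yy - 2.0 * (x @ y.transpose(1, 0))


def _kernel_matrix(x: Tensor, y: Tensor, config: LossConfig, sigma_sq: float) -> Tensor:
    if config.kernel == "linear":
        return x @ y.transpose(1, 0)
    if config.kernel == "polynomial":
        return (x @ y.transpose(1, 0) + 1.0) ** float(config.poly_degree)
    d = _pairwise_sq_dists(x, y)
    return (d * (-1.0 / (2.0 * sigma_sq))).exp()


def _mean_offdiag(k: Tensor) -> Tensor:
    n = k.shape[0]
    if n < 2:
        raise ValueError("unbiased estimator needs at least 2 samples per batch")
    diag_mask = Tensor(1.0 - np.eye(n, dtype=k.data.dtype))
    return (k * diag_mask).sum() * (1.0 / (n * (n - 1)))


def mmd_squared_graph(ms: Tensor, mt: Tensor, config: LossConfig) -> Tensor:
    """Differentiable squared-MMD between (Ns,D) and (Nt,D) batches."""
    if ms.shape[0] < 1 or mt.shape[0] < 1:
        raise ValueError("MMD requires non-empty batches")
    if ms.shape[1] != mt.shape[1]:
        raise ValueError(f"dimension mismatch: {ms.shape[1]} vs {mt.shape[1]}")
    sigma_sq = 1.0
    if config.kernel == "gaussian_rbf":
        if config.bandwidth == "median-heuristic":
            sigma_sq = _median_sq_bandwidth(ms.data, mt.data)
        else:
            sigma_sq = float(config.bandwidth) ** 2
    k_ss = _kernel_matrix(ms, ms, config, sigma_sq)
    k_tt = _kernel_matrix(mt, mt, config, sigma_sq)
    k_st = _kernel_matrix(ms, mt, config, sigma_sq)
    if config.unbiased:
        return _mean_offdiag(k_ss) + _mean_offdiag(k_tt) - 2.0 * k_st.mean()
    return k_ss.mean() + k_tt.mean() - 2.0 * k_st.mean()


def mmd_squared(ms_batch: np.ndarray, mt_batch: np.ndarray,
                config: LossConfig | None = None) -> float:
    """Squared-MMD estimate as a plain float (float64 arithmetic)."""
    config = config or LossConfig()
    ms = Tensor(np.atleast_2d(np.asarray(ms_batch, dtype=np.float64)))
    mt = Tensor(np.atleast_2d(np.asarray(mt_batch, dtype=np.float64)))
    return float(mmd_squared_graph(ms, mt, config).data)


def combined_loss(source_batch, target_batch, model, config: LossConfig,
                  *, training: bool = False,
                  rng: np.random.Generator | None = None):
    """Three-part objective on one (source, target) minibatch pair.

    ``model`` must expose ``forward_joint(xs, xt, training, rng)`` returning
    (source logits, target logits, source vectors, target vectors), where
    the vectors are the attention gates m (or GAP features in the ablated
    arm).  Returns ``(loss, components)`` with the loss still on the graph
    and components as floats {"ce_s", "ce_t", "mmd", "loss"}.
    """
    xs, ys = source_batch
    xt, yt = target_batch
    logits_s, logits_t, vs, vt = model.forward_joint(xs, xt, training=training, rng=rng)
    ce_s = _ce_graph(logits_s, ys)
    ce_t = _ce_graph(logits_t, yt)
    lam = config.lambda_disc
    if lam > 0:
        mmd = mmd_squared_graph(vs, vt, config)
        loss = ce_s + ce_t + lam * mmd
        mmd_val = float(mmd.data)
    else:
        mmd_val = 0.0
        loss = ce_s + ce_t
    components = {
        "ce_s": float(ce_s.data),
        "ce_t": float(ce_t.data),
        "mmd": mmd_val,
        "loss": float(loss.data),
    }
    return loss, components
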