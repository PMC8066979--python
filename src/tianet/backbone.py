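"""Base convolutional network: five conv layers plus two fully connected.

The seven weighted layers (conv1..conv5, fc1, fc2) are the unit of weight
transfer and freezing.  Each conv block is conv -> ReLU -> optional 2x2 max
pool; dropout precedes each FC layer.  Weights use He-style initialisation
from an explicit seed, so two builds with the same seed are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autograd import Tensor, conv2d, dropout, maxpool2d

__all__ = [
    "BackboneConfig",
    "Backbone",
    "build_backbone",
    "desk_config",
    "compact_config",
    "forward_features",
    "transfer_weights",
    "freeze_layers",
    "save_checkpoint",
    "load_checkpoint",
    "TransferError",
]

N_WEIGHTED_LAYERS = 7  # 5 conv + 2 FC


class TransferError(ValueError):
    """Raised when transferred layers are structurally incompatible."""


@dataclass(frozen=True)
class BackboneConfig:
    input_size: int = 64
    channels_per_conv: tuple[int, ...] = (16, 32, 64, 64, 32)
    kernel_sizes: tuple[int, ...] = (5, 3, 3, 3, 3)
    pool_after: tuple[int, ...] = (1, 2, 5)  # conv indices, 1-based
    fc_widths: tuple[int, int] = (128, 2)  # second entry = class count
    dropout_rate: float = 0.5
    #: conv biases start slightly positive so ReLUs don't die network-wide
    #: under momentum SGD at the default learning rate
    conv_bias_init: float = 0.1

    def __post_init__(self):
        if len(self.channels_per_conv) != 5 or len(self.kernel_sizes) != 5:
            raise ValueError("exactly five conv layers are required")
        if len(self.fc_widths) != 2:
            raise ValueError("exactly two FC layers are required")
        if any(c < 1 for c in self.channels_per_conv) or any(w < 1 for w in self.fc_widths):
            raise ValueError("layer widths must be positive")
        if any(k % 2 == 0 or k < 1 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd and positive")
        if any(p < 1 or p > 5 for p in self.pool_after):
            raise ValueError("pool_after entries must index conv layers 1..5")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.spatial_after(5) < 1:
            raise ValueError(
                "feature map collapses below 1x1; reduce pooling or grow input_size"
            )

    @property
    def n_classes(self) -> int:
        return self.fc_widths[1]

    def spatial_after(self, conv_index: int) -> int:
        """Side length of the feature map after conv block ``conv_index``.

        Convolutions are same-padded and stride 1, so only pooling shrinks
        the map (by 2 per pooled block).
        """
        size = self.input_size
        for i in range(1, conv_index + 1):
            if i in self.pool_after:
                if size % 2:
                    raise ValueError(f"odd spatial dim {size} before pool at conv{i}")
                size //= 2
        return size

    @property
    def flat_features(self) -> int:
        return self.channels_per_conv[-1] * self.spatial_after(5) ** 2

    def parameter_count(self) -> int:
        total, c_in = 0, 3
        for c_out, k in zip(self.channels_per_conv, self.kernel_sizes):
            total += c_out * c_in * k * k + c_out
            c_in = c_out
        d_in = self.flat_features
        for width in self.fc_widths:
            total += d_in * width + width
            d_in = width
        return total


def desk_config(n_classes: int = 2, input_size: int = 64) -> "BackboneConfig":
    """Default desk-scale architecture (the package's standard profile)."""
    return BackboneConfig(input_size=input_size, fc_widths=(128, n_classes))


def compact_config(n_classes: int = 2, input_size: int = 64) -> "BackboneConfig":
    """Narrow five-conv variant for CPU-bound experiments.

    Same 5+2 layer structure and pooling layout as the desk profile, with
    channel widths (8, 12, 16, 16, 16) and a 64-unit hidden FC so that full
    training runs complete in seconds per epoch on one core.
    """
    return BackboneConfig(
        input_size=input_size,
        channels_per_conv=(8, 12, 16, 16, 16),
        kernel_sizes=(5, 3, 3, 3, 3),
        pool_after=(1, 2, 5),
        fc_widths=(64, n_classes),
    )


class Backbone:
    """Model handle: ordered (weight, bias) tensor pairs for the 7 layers."""

    def __init__(self, config: BackboneConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list[tuple[Tensor, Tensor]] = []
        c_in = 3
        for c_out, k in zip(config.channels_per_conv, config.kernel_sizes):
            fan_in = c_in * k * k
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
            bias = np.full(c_out, config.conv_bias_init, dtype=np.float32)
            self.layers.append(
                (Tensor(w.astype(np.float32), requires_grad=True),
                 Tensor(bias, requires_grad=True))
            )
            c_in = c_out
        d_in = config.flat_features
        for width in config.fc_widths:
            w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, width))
            self.layers.append(
                (Tensor(w.astype(np.float32), requires_grad=True),
                 Tensor(np.zeros(width, dtype=np.float32), requires_grad=True))
            )
            d_in = width

    # -- forward passes ----------------------------------------------------

    def _conv_stack(self, x: Tensor, upto: int) -> Tensor:
        cfg = self.config
        for i in range(upto):
            w, b = self.layers[i]
            x = conv2d(x, w, b, padding=cfg.kernel_sizes[i] // 2).relu()
            if (i + 1) in cfg.pool_after:
                x = maxpool2d(x, 2)
        return x

    def head(self, feats: Tensor, *, training: bool = False,
             rng: np.random.Generator | None = None,
             layers: list[tuple[Tensor, Tensor]] | None = None) -> Tensor:
        """FC classifier on flattened conv features (dropout before each FC)."""
        cfg = self.config
        fc1, fc2 = (layers or self.layers[5:7])
        n = feats.shape[0]
        x = feats.reshape(n, -1)
        x = dropout(x, cfg.dropout_rate, rng, training)
        x = (x @ fc1[0] + fc1[1]).relu()
        x = dropout(x, cfg.dropout_rate, rng, training)
        return x @ fc2[0] + fc2[1]

    def forward(self, batch: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Logits for an (N, 3, H, W) batch."""
        x = Tensor(np.ascontiguousarray(batch, dtype=np.float32))
        feats = self._conv_stack(x, 5)
        return self.head(feats, training=training, rng=rng)

    # -- parameter bookkeeping --------------------------------------------

    def parameters(self) -> list[Tensor]:
        return [t for pair in self.layers for t in pair]

    def layer_parameters(self, index: int) -> tuple[Tensor, Tensor]:
        """1-based access to the weighted layers (1..7)."""
        if not 1 <= index <= N_WEIGHTED_LAYERS:
            raise IndexError(f"layer index {index} outside 1..{N_WEIGHTED_LAYERS}")
        return self.layers[index - 1]

    def trainable_parameters(self, freeze_k: int = 0) -> list[Tensor]:
        """Parameters of layers freeze_k+1 .. 7 (layers 1..freeze_k frozen)."""
        if not 0 <= freeze_k <= N_WEIGHTED_LAYERS:
            raise ValueError(f"freeze_k must lie in 0..{N_WEIGHTED_LAYERS}")
        return [t for pair in self.layers[freeze_k:] for t in pair]

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([t.data.ravel() for t in self.parameters()])


# ---------------------------------------------------------------------------
# Spec-level operations (thin functional wrappers)
# ---------------------------------------------------------------------------


def build_backbone(config: BackboneConfig, seed: int) -> Backbone:
    return Backbone(config, seed)


def forward_features(model: Backbone, batch: np.ndarray, upto_layer: int) -> Tensor:
    """Activations after conv block ``upto_layer`` (post-ReLU/pool).

    Only the five conv blocks produce spatial feature maps.
    """
    if not 1 <= upto_layer <= 5:
        raise ValueError("upto_layer must lie in 1..5 (FC layers have no spatial map)")
    x = Tensor(np.ascontiguousarray(batch, dtype=np.float32))
    return model._conv_stack(x, upto_layer)


def transfer_weights(source: Backbone, target: Backbone, k: int) -> Backbone:
    """Copy layers 1..k from source into target; layers k+1.. untouched."""
    if not 0 <= k <= N_WEIGHTED_LAYERS:
        raise ValueError(f"k must lie in 0..{N_WEIGHTED_LAYERS}")
    for i in range(1, k + 1):
        (ws, bs), (wt, bt) = source.layer_parameters(i), target.layer_parameters(i)
        if ws.shape != wt.shape or bs.shape != bt.shape:
            raise TransferError(
                f"layer {i} shape mismatch: source {ws.shape} vs target {wt.shape}"
            )
    for i in range(1, k + 1):
        (ws, bs), (wt, bt) = source.layer_parameters(i), target.layer_parameters(i)
        wt.data = ws.data.copy()
        bt.data = bs.data.copy()
    return target


def freeze_layers(model: Backbone, k: int) -> list[Tensor]:
    """Return the trainable parameter list with layers 1..k excluded.

    Freezing is enforced by handing only this list to the optimizer; frozen
    tensors are never written, so they stay bit-identical.
    """
    return model.trainable_parameters(freeze_k=k)


# ---------------------------------------------------------------------------
# Checkpointing: npz weights + JSON sidecar with config and seed
# ---------------------------------------------------------------------------


def save_checkpoint(model: Backbone, path: str | Path) -> None:
    path = Path(path)
    arrays = {}
    for i, (w, b) in enumerate(model.layers, start=1):
        arrays[f"w{i}"] = w.data
        arrays[f"b{i}"] = b.data
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"config": asdict(model.config), "seed": model.seed}))


def load_checkpoint(path: str | Path) -> Backbone:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = meta["config"]
    for key in ("channels_per_conv", "kernel_sizes", "pool_after", "fc_widths"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = Backbone(BackboneConfig(**cfg_dict), seed=meta["seed"])
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        for i, (w, b) in enumerate(model.layers, start=1):
            w.data = data[f"w{i}"].copy()
            b.data = data[f"b{i}"].copy()
    return model
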