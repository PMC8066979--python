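"""Training orchestration: source pretraining, weight transfer, joint
training with the combined objective, and the layer-sweep experiment.

The protocol has two phases.  First the base CNN is pretrained on the
source (cataract-grade) task with plain cross-entropy.  Then its first
``k`` weighted layers are copied into a fresh target network and the joint
phase minimises

    Loss = CE(source) + CE(target) + lambda * MMD^2(m_s, m_t)

over paired minibatches, one drawn from each dataset per step (the source
stream is cycled; an epoch is one pass over the target set).  In ``frozen``
mode the transferred layers are excluded from the optimizer and therefore
stay bit-identical; ``finetune`` updates everything; ``scratch`` trains the
target network alone on target cross-entropy (the no-transfer baseline).

When the attention head is ablated (``use_attention=False``) the
discrepancy needs some vector to compare: the GAP of the conv features
stands in for the attention gates so the objective stays well-defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

from ._autograd import SGD, Tensor, cross_entropy as ce_graph
from .attention import ChannelAttention
from .backbone import Backbone, BackboneConfig, build_backbone, transfer_weights
from .evaluation import MetricsReport, roc_auc
from .losses import LossConfig, combined_loss
from .synthetic_fundus import LabeledDataset

__all__ = [
    "TrainSchedule",
    "TransferPlan",
    "TIANet",
    "pretrain_source",
    "run_transfer",
    "layer_sweep",
    "augment",
    "predict_proba",
    "DESK_SCHEDULE",
]


@dataclass(frozen=True)
class TrainSchedule:
    """SGD hyperparameters; defaults follow the full-scale training profile."""

    epochs: int = 100
    batch_size: int = 16
    lr: float = 1e-2
    momentum: float = 0.9
    weight_decay: float = 5e-4
    lr_step_epochs: int = 30
    lr_gamma: float = 0.1
    seed: int = 0
    augmentations: tuple = ()
    #: global gradient-norm clip; None disables (guards the joint phase
    #: against occasional gradient explosion at the default learning rate)
    clip_norm: float | None = 5.0

    def lr_at(self, epoch: int) -> float:
        return self.lr * self.lr_gamma ** (epoch // self.lr_step_epochs)


#: CPU-scale profile used throughout the tests and worked examples
DESK_SCHEDULE = TrainSchedule(epochs=10, batch_size=16, lr_step_epochs=5)

_MODES = ("frozen", "finetune", "scratch")


@dataclass(frozen=True)
class TransferPlan:
    transfer_k: int = 5
    mode: str = "finetune"
    use_attention: bool = True
    loss: LossConfig = field(default_factory=LossConfig)
    schedule: TrainSchedule = field(default_factory=lambda: DESK_SCHEDULE)

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not 0 <= self.transfer_k <= 7:
            raise ValueError("transfer_k must lie in 0..7")


# ---------------------------------------------------------------------------
# Data helpers
# ---------------------------------------------------------------------------


def _to_nchw(images: list[np.ndarray]) -> np.ndarray:
    return np.stack(images).astype(np.float32).transpose(0, 3, 1, 2)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _BatchStream:
    """Endless shuffled minibatch stream over a dataset (cycling epochs)."""

    def __init__(self, dataset: LabeledDataset, batch_size: int, seed: int,
                 augmentations: tuple = ()):
        self.x = _to_nchw(dataset.images)
        self.y = np.asarray(dataset.labels)
        self.batch = batch_size
        self.rng = np.random.default_rng(seed)
        self.augmentations = tuple(augmentations)
        self._order = self.rng.permutation(len(self.y))
        self._pos = 0
        self._step = 0

    def next(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.y)
        if self._pos >= n:
            self._order = self.rng.permutation(n)
            self._pos = 0
        idx = self._order[self._pos : self._pos + self.batch]
        self._pos += self.batch
        xb = self.x[idx]
        if self.augmentations:
            xb = np.stack(
                [
                    augment(im.transpose(1, 2, 0), self.augmentations,
                            seed=int(self.rng.integers(0, 2**31 - 1))).transpose(2, 0, 1)
                    for im in xb
                ]
            ).astype(np.float32)
        self._step += 1
        return xb, self.y[idx]


# ---------------------------------------------------------------------------
# TIA-Net model: shared trunk + attention + two task heads
# ---------------------------------------------------------------------------


class TIANet:
    """Transfer-induced attention network.

    Shares the five conv blocks of the target backbone between a source
    head (class count of the pretraining task) and the target head
    (= FC layers 6-7 of the backbone).  Attention sits on the conv-5
    feature map; both batches pass through it, and their gate vectors
    feed the discrepancy term.
    """

    def __init__(self, backbone: Backbone, source_head: list[tuple[Tensor, Tensor]],
                 attention: ChannelAttention | None):
        self.backbone = backbone
        self.source_head = source_head
        self.attention = attention

    @property
    def use_attention(self) -> bool:
        return self.attention is not None

    def _features(self, x: np.ndarray) -> Tensor:
        t = Tensor(np.ascontiguousarray(x, dtype=np.float32))
        return self.backbone._conv_stack(t, 5)

    def _specific(self, G: Tensor) -> tuple[Tensor, Tensor]:
        """(P, vector-for-MMD) — gates m, or GAP(G) in the ablated arm."""
        if self.attention is not None:
            return self.attention(G)
        n, c, h, w = G.shape
        return G, G.reshape(n, c, h * w).mean(axis=2)

    def forward_joint(self, xs, xt, *, training: bool = False,
                      rng: np.random.Generator | None = None):
        Gs, Gt = self._features(xs), self._features(xt)
        Ps, vs = self._specific(Gs)
        Pt, vt = self._specific(Gt)
        logits_s = self.backbone.head(Ps, training=training, rng=rng,
                                      layers=self.source_head)
        logits_t = self.backbone.head(Pt, training=training, rng=rng)
        return logits_s, logits_t, vs, vt

    def forward_target(self, xt, *, training: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        G = self._features(xt)
        P, _ = self._specific(G)
        return self.backbone.head(P, training=training, rng=rng)

    def specific_feature(self, image: np.ndarray) -> np.ndarray:
        """Attention-reweighted conv-5 feature map P for one HWC image."""
        x = image[None].transpose(0, 3, 1, 2)
        G = self._features(x)
        P, _ = self._specific(G)
        return P.data[0]

    def trainable_parameters(self, freeze_k: int = 0) -> list[Tensor]:
        params = self.backbone.trainable_parameters(freeze_k)
        params += [t for pair in self.source_head for t in pair]
        if self.attention is not None:
            params += self.attention.parameters()
        return params


def predict_proba(model, images: list[np.ndarray], batch_size: int = 64) -> np.ndarray:
    """Class probabilities in eval mode (dropout off), batched for memory."""
    x = _to_nchw(images)
    out = []
    for i in range(0, len(x), batch_size):
        xb = x[i : i + batch_size]
        if isinstance(model, TIANet):
            logits = model.forward_target(xb)
        else:
            logits = model.forward(xb)
        out.append(_softmax(logits.data))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Phase 1: source pretraining
# ---------------------------------------------------------------------------


def pretrain_source(dataset: LabeledDataset, config: BackboneConfig,
                    schedule: TrainSchedule) -> tuple[Backbone, pd.DataFrame]:
    """Train the base CNN on the source task with plain cross-entropy."""
    if config.n_classes != dataset.n_classes:
        raise ValueError(
            f"config has {config.n_classes} output units but task "
            f"{dataset.task} has {dataset.n_classes} classes"
        )
    model = build_backbone(config, seed=schedule.seed)
    rng = np.random.default_rng(schedule.seed + 1)
    stream = _BatchStream(dataset, schedule.batch_size, seed=schedule.seed + 2,
                          augmentations=schedule.augmentations)
    opt = SGD(model.parameters(), lr=schedule.lr, momentum=schedule.momentum,
              weight_decay=schedule.weight_decay, clip_norm=schedule.clip_norm)
    steps_per_epoch = math.ceil(len(dataset) / schedule.batch_size)
    rows = []
    step = 0
    for epoch in range(schedule.epochs):
        opt.lr = schedule.lr_at(epoch)
        for _ in range(steps_per_epoch):
            xb, yb = stream.next()
            logits = model.forward(xb, training=True, rng=rng)
            loss = ce_graph(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            acc = float((logits.data.argmax(1) == yb).mean())
            rows.append({"epoch": epoch, "step": step, "loss": float(loss.data),
                         "acc": acc, "lr": opt.lr})
            step += 1
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phase 2: joint transfer training
# ---------------------------------------------------------------------------


def run_transfer(source_model: Backbone | None, source_ds: LabeledDataset | None,
                 target_ds: LabeledDataset, plan: TransferPlan,
                 on_step=None) -> tuple[TIANet, pd.DataFrame]:
    """Joint training of the target network under a transfer plan.

    Returns the trained model and the per-step component log with columns
    ``step, loss, ce_s, ce_t, mmd, lr``.  ``on_step(step, model)``, if
    given, is invoked with the untrained model at step 0 and again after
    every optimizer update — the hook behind iteration-snapshot heatmaps.
    """
    sched = plan.schedule
    scratch = plan.mode == "scratch"
    if not scratch and (source_model is None or source_ds is None):
        raise ValueError("frozen/finetune modes require a source model and dataset")
    if plan.mode == "frozen" and plan.transfer_k == 0:
        warnings.warn("frozen mode with transfer_k=0 is equivalent to scratch",
                      UserWarning, stacklevel=2)

    if scratch:
        base_cfg = source_model.config if source_model is not None else BackboneConfig()
    else:
        base_cfg = source_model.config
    tgt_cfg = replace(base_cfg, fc_widths=(base_cfg.fc_widths[0], target_ds.n_classes),
                      input_size=target_ds.images[0].shape[0])
    target_model = build_backbone(tgt_cfg, seed=sched.seed + 10)
    if not scratch:
        transfer_weights(source_model, target_model, plan.transfer_k)

    attention = None
    if plan.use_attention:
        attention = ChannelAttention(tgt_cfg.channels_per_conv[-1],
                                     seed=sched.seed + 20)
    if scratch:
        source_head = []
    else:
        source_head = [
            (Tensor(w.data.copy(), requires_grad=True),
             Tensor(b.data.copy(), requires_grad=True))
            for (w, b) in source_model.layers[5:7]
        ]
    model = TIANet(target_model, source_head, attention)

    freeze_k = plan.transfer_k if plan.mode == "frozen" else 0
    opt = SGD(model.trainable_parameters(freeze_k), lr=sched.lr,
              momentum=sched.momentum, weight_decay=sched.weight_decay,
              clip_norm=sched.clip_norm)
    rng = np.random.default_rng(sched.seed + 30)
    t_stream = _BatchStream(target_ds, sched.batch_size, seed=sched.seed + 40,
                            augmentations=sched.augmentations)
    s_stream = None
    if not scratch:
        s_stream = _BatchStream(source_ds, sched.batch_size, seed=sched.seed + 50,
                                augmentations=sched.augmentations)

    steps_per_epoch = math.ceil(len(target_ds) / sched.batch_size)
    rows = []
    step = 0
    if on_step is not None:
        on_step(0, model)
    for epoch in range(sched.epochs):
        opt.lr = sched.lr_at(epoch)
        for _ in range(steps_per_epoch):
            xt, yt = t_stream.next()
            if scratch:
                logits_t = model.forward_target(xt, training=True, rng=rng)
                loss = ce_graph(logits_t, yt)
                comps = {"ce_s": 0.0, "ce_t": float(loss.data), "mmd": 0.0,
                         "loss": float(loss.data)}
            else:
                xs, ys = s_stream.next()
                loss, comps = combined_loss((xs, ys), (xt, yt), model, plan.loss,
                                            training=True, rng=rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            rows.append({"step": step, **comps, "lr": opt.lr})
            step += 1
            if on_step is not None:
                on_step(step, model)
    return model, pd.DataFrame(rows)


def evaluate_on(model, dataset: LabeledDataset) -> MetricsReport:
    """Accuracy/sensitivity/specificity/AUC of a binary classifier."""
    probs = predict_proba(model, dataset.images)[:, 1]
    return MetricsReport.from_scores(dataset.labels, probs)


# ---------------------------------------------------------------------------
# Layer-sweep experiment
# ---------------------------------------------------------------------------


def layer_sweep(source_model: Backbone, source_ds: LabeledDataset,
                target_train: LabeledDataset, target_test: LabeledDataset,
                ks: list[int], modes: list[str], schedule: TrainSchedule,
                seeds: list[int], *, use_attention: bool = True,
                loss: LossConfig | None = None,
                out_csv=None) -> pd.DataFrame:
    """Train/evaluate every (k, mode, seed) combination.

    Emits one tidy row per run with held-out accuracy and AUC, optionally
    written to CSV.
    """
    loss = loss or LossConfig()
    rows = []
    for k in ks:
        for mode in modes:
            for seed in seeds:
                plan = TransferPlan(transfer_k=k, mode=mode,
                                    use_attention=use_attention, loss=loss,
                                    schedule=replace(schedule, seed=seed))
                model, _ = run_transfer(source_model, source_ds, target_train, plan)
                rep = evaluate_on(model, target_test)
                rows.append({"k": k, "mode": mode, "seed": seed,
                             "accuracy": rep.accuracy, "auc": rep.auc})
    frame = pd.DataFrame(rows)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _parse_op(op) -> tuple[str, float | None]:
    if isinstance(op, (tuple, list)):
        name, arg = op[0], (op[1] if len(op) > 1 else None)
    elif isinstance(op, str) and ":" in op:
        name, arg_s = op.split(":", 1)
        arg = float(arg_s)
    else:
        name, arg = op, None
    return str(name), arg


def augment(image: np.ndarray, ops, seed: int = 0) -> np.ndarray:
    """Apply label-preserving transforms to one HWC image, deterministically.

    Supported ops: ``hflip``; ``("rotation", deg)`` rotating by an angle
    drawn uniformly from [-deg, deg]; ``("random_crop", pad)`` reflect-
    padding by ``pad`` then cropping back at a random offset.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(image)
    for op in ops:
        name, arg = _parse_op(op)
        if name == "hflip":
            out = out[:, ::-1]
        elif name == "rotation":
            deg = float(arg or 0.0)
            angle = float(rng.uniform(-deg, deg))
            if angle != 0.0:
                out = _sk_rotate(out, angle, order=1, mode="edge",
                                 preserve_range=True)
        elif name == "random_crop":
            pad = int(arg or 0)
            if pad > 0:
                h, w = out.shape[:2]
                padded = np.pad(out, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
                dy, dx = rng.integers(0, 2 * pad + 1, size=2)
                out = padded[dy : dy + h, dx : dx + w]
        else:
            raise ValueError(f"unknown augmentation op {name!r}")
    return np.ascontiguousarray(out)
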