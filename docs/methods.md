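# Methods

## Problem and model

Glaucoma screening from fundus photographs is label-starved: clinical
glaucoma datasets are small, while related ophthalmic imagery (e.g. cataract
grading photographs) is comparatively plentiful and shares the same
low-level appearance — optic disc, cup, vasculature on a reddish eyeball.
The package implements a transfer-induced attention network that exploits
this: a base CNN is pretrained on a *source* cataract-grading task, its
shallow layers are transferred to a *target* glaucoma classifier, and a
channel-wise attention head plus a distribution-matching penalty steer the
transferred representation toward glaucoma-relevant structure.

The base network has seven weighted layers — five convolutions (each
conv → ReLU, with 2×2 max-pooling after blocks 1, 2 and 5) and two fully
connected layers with dropout before each.  "Layer k" in every transfer or
freeze operation counts these seven weighted layers in order.

Channel attention operates on the conv-5 feature map `G ∈ R^{C×H×W}`:

    o_c = (1/WH) Σ_ij G_c(i,j)              (global average pooling)
    m   = σ(W1 (W0 o))                       (two-layer recalibration)
    P_c = m_c · G_c                          (channel-wise reweighting)

As printed above there is **no nonlinearity between W0 and W1**; this is the
composition the model uses by default, with an optional inner-ReLU flag for
comparison with the squeeze-excitation convention.  Biases on both maps are
included by default (toggleable).  The bottleneck width is `max(C/4, 4)`.

Joint training minimises, over paired minibatches (one from each dataset),

    Loss = CE(X_s, Y_s) + CE(X_t, Y_t) + λ · MMD²(m_s, m_t)

where `m_s`, `m_t` are the per-sample attention gate vectors of the source
and target batches and MMD² is the squared Maximum Mean Discrepancy — the
RKHS distance between the empirical kernel mean embeddings, estimated with
the biased V-statistic

    (1/N_s²)Σ k(s,s′) + (1/N_t²)Σ k(t,t′) − (2/(N_s N_t))Σ k(s,t).

An unbiased U-statistic variant exists behind a flag.  In the
attention-ablated arm (plain CNN) the discrepancy is computed on GAP(G)
instead, so the objective stays defined; this is an artifact decision, not
part of the attended model.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| λ (discrepancy weight) | 1.0 | dimensionless; no canonical value exists, exposed everywhere |
| kernel | Gaussian RBF | bandwidth σ² = median of pooled pairwise squared distances of the current batch pair (floored at 1e-3), treated as a constant of the step (not differentiated) |
| learning rate | 1e-2 | SGD with momentum 0.9, step decay ×0.1; the study experiments pretrain at this rate and run the joint phase at the conventional fine-tuning rate 3e-3 |
| gradient clip | 5.0 (global norm) | `TrainSchedule.clip_norm`; `None` disables |
| batch size | 16 | one batch per dataset per step |
| weight decay | 5e-4 | L2 penalty |
| dropout | 0.5 | before each FC layer |
| epochs | 100 (full profile) / 10 (desk) | fixed; no early stopping |
| decision threshold | 0.5 | on the softmax positive-class probability; AUC is threshold-free |

Epoch length in joint training is one pass over the target set; the source
stream is cycled with an independent shuffle.  Frozen layers are enforced by
excluding their tensors from the optimizer, so "frozen" is bitwise exact.
`scratch` mode trains the target network on target cross-entropy alone (the
no-transfer CNN baseline); its log keeps the `ce_s`/`mmd` columns at zero so
the decomposition `loss = ce_s + ce_t + λ·mmd` holds for every mode.

## Synthetic fundus generator

Clinical fundus datasets cannot ship with the package, so a deterministic
generator emulates their *structure*: a dark field with a reddish eyeball
disc, a brighter vertically-elliptical optic disc containing a pale cup
(cup radii = CDR × disc radii, shared centre), dark recursive branching
vessels seeded at the disc edge, an optional greenish peripapillary-atrophy
annulus, cataract haze (Gaussian blur + brightness washout, both scaled by
`haze_level`) and additive Gaussian pixel noise.  Ground truth follows the
clinical conventions the tasks are built on:

* glaucoma label = 1 iff CDR > 0.5 (strict; the boundary is negative);
* cataract grade = haze bin, edges at 0.25 / 0.5 / 0.75 — four equal bins,
  a stand-in for clinical grading standards that are not quantitatively
  specified anywhere; the edges are configurable.

Vessel width shrinks with branch depth so that mild haze erases fine
distal vessels before thick trunks, mirroring how cataract severity is read.
Default rendering parameters: disc centre jittered in [0.4, 0.6]², disc
radius rx ∈ [0.10, 0.15] with ry/rx ∈ [1.1, 1.35], 4–7 vessels, noise SD
0.02.  Target-task scenes are haze-free; source-task scenes span the full
CDR range so haze is the only systematic source signal.  PPA is drawn with
probability 0.5 for glaucomatous scenes and 0.15 otherwise — correlated
with, but never used by, the label.

What this generator does **not** emulate: photographic vignetting and
illumination fields, RNFL texture and wedge defects, camera-specific colour
response, anatomical variability of real discs, label noise.  Passing tests
therefore demonstrate that the *mechanism* (transfer + attention + MMD)
behaves as specified on data with the right causal structure — not that the
trained models would reach clinical accuracy on real photographs.

## Problem sizes and profiles

Training runs entirely on CPU through a compact numpy autodiff engine
(im2col convolutions on BLAS, reverse-mode graph), so experiment sizes are
chosen at "desk scale":

* **desk profile** — 64-px images, channels (16, 32, 64, 64, 32), kernels
  (5, 3, 3, 3, 3), FC widths (128, classes), 10 epochs;
* **compact profile** (`tianet.compact_config`) — same 5+2 structure with
  channels (8, 12, 16, 16, 16) and a 64-unit FC; used by the study-scale
  experiments and the acceptance script so that a full pretrain + sweep
  completes in minutes on one core;
* **full profile** — 256-px input, 100 epochs, available through the
  configuration presets for anyone with the patience.

The study conditions of the stochastic experiments are fixed: source
n = 400 (4 balanced grades), target n = 100 train / 100 test (balanced),
64 px, batch 16; the source model is pretrained to convergence (30 epochs,
lr 1e-2) and every joint arm trains 10 epochs at the fine-tuning rate
3e-3, with five repeat seeds in the test suite (three in the acceptance
script).  All arms — scratch CNN, frozen and fine-tuned transfer, with and
without attention — share the compact architecture.  The layer sweep
covers k ∈ {4, 6} for frozen and fine-tune modes; k = 7 is impossible
between heads with different class counts, and the deep-transfer
comparison aggregates over k ≥ 4, where the frozen-transfer decline is
expected.

## Numerical choices

* Convolution biases start at 0.1 (`BackboneConfig.conv_bias_init`; zero
  restores the textbook He setup): with zero biases, momentum SGD at the
  default rate killed every ReLU channel for roughly one in four
  initialisation seeds, pinning the loss at chance.
* Gradients are clipped to global norm 5 and a non-finite gradient skips
  the update; the RBF bandwidth floor (σ² ≥ 1e-3) prevents the 1/σ²
  gradient blow-up once source and target gate distributions have been
  pulled together.
* All tensors in training are float32; the algebraic oracle surfaces
  (`global_average_pool`, `channel_attention`, `reweight`, `mmd_squared`,
  metrics) compute in float64.
* Attention gates are clamped to the open interval (0, 1) at machine
  margin, since the exact sigmoid saturates in floating point for
  |pre-activation| ≳ 37.
* Max-pool backward splits gradient evenly among tied maxima, keeping the
  backward pass deterministic.
* Sensitivity/specificity with a zero denominator return NaN with a
  `RuntimeWarning` rather than raising.
* Heatmaps aggregate channels by mean absolute activation (max available),
  min-max normalise (a constant map becomes all-zeros), and upsample
  bilinearly (nearest available for exact tests).
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; there is no global RNG state, and two runs with
  the same seeds are bit-identical on the same platform/BLAS.

## Design choices where the design was open

* **Joint-phase heads.** The source cross-entropy needs source logits after
  transfer: the model keeps a source head (a copy of the pretrained FC
  stack) on the shared trunk, trained alongside.  Both batches pass through
  the same attention module, which is what makes `m_s` and `m_t`
  comparable.
* **Freezing indexation** covers the seven weighted layers of the target
  network (trunk + target head); the auxiliary source head and the
  attention parameters always train.
* **Class interleaving** in generated datasets keeps contiguous slices
  label-mixed so small minibatches see both classes.
* **Stratified folds** in cross-validation guarantee both classes per fold
  at small n; fold metrics are reported per fold with mean and variance.

## Known limitations

* The engine implements exactly the operations this architecture needs;
  there is no GPU path, stride support, or batch-norm.
* The compact profile's absolute AUCs depend on the synthetic tasks'
  difficulty; only directions (transfer ≥ scratch, fine-tune ≥ frozen at
  deep k, localization growth) are meaningful claims.
* Median-heuristic bandwidth is recomputed per step from the current batch
  pair, so the MMD scale can drift early in training.
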