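"""Attention heatmaps and localization scoring.

The specific feature P (the attention-reweighted conv feature map) is
collapsed across channels, min-max normalized, and upsampled to image size;
overlaying it on the input with a warm-to-cool colormap shows which regions
the network currently weights for the diagnosis.  The localization score
measures what fraction of heatmap mass falls inside a ground-truth
pathology mask (here, the optic-disc ellipse), so heatmap evolution over
training iterations can be quantified.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize

__all__ = ["attention_heatmap", "overlay", "localization_score", "save_panel"]


def attention_heatmap(P: np.ndarray, out_size: int, *, aggregate: str = "mean_abs",
                      upsample: str = "bilinear") -> np.ndarray:
    """Collapse (C,H,W) to a [0,1] heatmap of side ``out_size``.

    Channels are aggregated by the mean of absolute activations (or the
    max, with ``aggregate="max"``); a constant map normalizes to all-zeros.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 3:
        raise ValueError(f"expected (C,H,W), got shape {P.shape}")
    if not np.isfinite(P).all():
        raise ValueError("P contains non-finite values")
    if aggregate == "mean_abs":
        h = np.abs(P).mean(axis=0)
    elif aggregate == "max":
        h = P.max(axis=0)
    else:
        raise ValueError("aggregate must be 'mean_abs' or 'max'")
    lo, hi = h.min(), h.max()
    h = np.zeros_like(h) if hi - lo <= 0 else (h - lo) / (hi - lo)
    order = 1 if upsample == "bilinear" else 0
    if upsample not in ("bilinear", "nearest"):
        raise ValueError("upsample must be 'bilinear' or 'nearest'")
    out = resize(h, (out_size, out_size), order=order, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def overlay(image: np.ndarray, heatmap: np.ndarray, colormap: str = "jet") -> np.ndarray:
    """Alpha-blend a warm-to-cool colormap over the image, pixel-locally.

    Blend weight equals the heatmap value, so zero-heat pixels reproduce the
    input and saturated pixels show the pure warm colour.
    """
    image = np.asarray(image, dtype=float)
    heatmap = np.asarray(heatmap, dtype=float)
    if image.shape[:2] != heatmap.shape:
        raise ValueError(
            f"size mismatch: image {image.shape[:2]} vs heatmap {heatmap.shape}"
        )
    cmap = colormaps[colormap]
    colors = cmap(heatmap)[..., :3]
    alpha = heatmap[..., None]
    return np.clip((1.0 - alpha) * image + alpha * colors, 0.0, 1.0)


def localization_score(heatmap: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of heatmap mass inside the mask (0 for an all-zero heatmap)."""
    heatmap = np.asarray(heatmap, dtype=float)
    mask = np.asarray(mask)
    if heatmap.shape != mask.shape:
        raise ValueError("heatmap and mask must share shape")
    if not np.isin(mask, (0, 1)).all() and mask.dtype != bool:
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    total = heatmap.sum()
    if total <= 0:
        return 0.0
    return float(heatmap[mask].sum() / total)


def save_panel(images: list[np.ndarray], path, titles: list[str] | None = None) -> None:
    """Write a horizontal panel of [0,1] RGB images as one 8-bit PNG."""
    arrs = [(np.asarray(im) * 255).round().astype(np.uint8) for im in images]
    h = max(a.shape[0] for a in arrs)
    pad = 2
    w = sum(a.shape[1] for a in arrs) + pad * (len(arrs) - 1)
    canvas = np.full((h, w, 3), 255, dtype=np.uint8)
    x = 0
    for a in arrs:
        canvas[: a.shape[0], x : x + a.shape[1]] = a
        x += a.shape[1] + pad
    Image.fromarray(canvas).save(path)
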