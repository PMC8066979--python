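"""Seeded generator of synthetic fundus-like images.

Real fundus photographs show a dark reddish eyeball disc with a brighter,
vertically elliptical optic disc whose center contains a pale cup; dark blood
vessels radiate from the disc, and glaucomatous eyes may show a greenish
peripapillary-atrophy (PPA) annulus.  Cataract degrades the whole photograph
with haze: blur plus brightness washout that erases small vessels first, then
large ones.  This module renders such scenes deterministically from explicit
parameters, so that

* the **source task** (cataract grading, 4 classes) is driven by haze level,
* the **target task** (glaucoma detection, binary) is driven by the
  cup-to-disc ratio (CDR), with the conventional CDR > 0.5 warning threshold
  as ground truth,

and both tasks share low-level appearance (disc, cup, vessels), which is what
makes features transferable between them.  Ground-truth optic-disc masks are
available for localization scoring of attention heatmaps.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "FundusSceneParams",
    "LabeledDataset",
    "render_fundus",
    "glaucoma_label",
    "cataract_label",
    "pathology_mask",
    "generate_dataset",
    "SOURCE_TASK",
    "TARGET_TASK",
]

SOURCE_TASK = "source_cataract"
TARGET_TASK = "target_glaucoma"
N_CLASSES = {SOURCE_TASK: 4, TARGET_TASK: 2}

#: haze-level bin edges mapping to cataract grades 0..3 (configurable)
CATARACT_BIN_EDGES = (0.25, 0.5, 0.75)

#: CDR above which the scene is labelled glaucomatous (strict inequality)
GLAUCOMA_CDR_THRESHOLD = 0.5


@dataclass(frozen=True)
class FundusSceneParams:
    """Generative parameters of one synthetic fundus scene.

    Coordinates and radii are normalized to the unit square; the optic disc
    is a vertical ellipse (``ry >= rx``) and the cup is the concentric
    ellipse with radii scaled by ``cup_to_disc_ratio``.
    """

    image_size: int = 64
    disc_center: tuple[float, float] = (0.5, 0.5)
    disc_radii: tuple[float, float] = (0.13, 0.16)  # (rx, ry), ry >= rx
    cup_to_disc_ratio: float = 0.4
    vessel_count: int = 5
    vessel_seed: int = 0
    haze_level: float = 0.0
    ppa_present: bool = False
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rx, ry = self.disc_radii
        if not (0.0 < rx <= 1.0 and 0.0 < ry <= 1.0):
            raise ValueError(f"disc radii must lie in (0, 1], got {self.disc_radii}")
        if ry < rx:
            raise ValueError("optic disc must be a vertical ellipse (ry >= rx)")
        if not (0.1 <= self.cup_to_disc_ratio <= 0.95):
            raise ValueError(
                f"cup_to_disc_ratio must lie in [0.1, 0.95], got {self.cup_to_disc_ratio}"
            )
        if not (0.0 <= self.haze_level <= 1.0):
            raise ValueError(f"haze_level must lie in [0, 1], got {self.haze_level}")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")

    def digest(self) -> str:
        payload = repr(dataclasses.astuple(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class LabeledDataset:
    """In-memory dataset: RGB float images in [0,1] plus integer labels."""

    images: list[np.ndarray]
    labels: np.ndarray
    task: str
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: generative parameters per image, when the dataset was synthesized
    scene_params: list[FundusSceneParams] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.task not in N_CLASSES:
            raise ValueError(f"unknown task {self.task!r}")
        k = N_CLASSES[self.task]
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError(f"labels outside [0,{k}) for task {self.task}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return N_CLASSES[self.task]

    def as_array(self) -> np.ndarray:
        """Stack to (N, H, W, 3) float32."""
        return np.stack(self.images).astype(np.float32)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_BACKGROUND = np.array([0.02, 0.02, 0.02])
_EYEBALL = np.array([0.55, 0.17, 0.07])
_DISC = np.array([0.93, 0.72, 0.42])
_CUP = np.array([0.99, 0.93, 0.82])
_PPA = np.array([0.45, 0.60, 0.25])
_VESSEL = np.array([0.32, 0.05, 0.04])
_HAZE_TINT = np.array([0.80, 0.78, 0.72])


def _pixel_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pixel-center coordinates (x right, y down)."""
    c = (np.arange(size) + 0.5) / size
    return np.meshgrid(c, c)  # X (cols), Y (rows)


def _ellipse_mask(size: int, center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    x, y = _pixel_grid(size)
    cx, cy = center
    rx, ry = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def _draw_vessels(img: np.ndarray, params: FundusSceneParams) -> None:
    """Recursive branching polylines seeded at the disc edge, drawn in place.

    Trunk width shrinks with branch depth so that mild haze erases the fine
    distal branches before the thick trunks, mirroring how cataract grades
    are read off vessel visibility.
    """
    size = params.image_size
    rng = np.random.default_rng(params.vessel_seed)
    cx, cy = params.disc_center
    rx, ry = params.disc_radii

    def stamp(px: float, py: float, width: float) -> None:
        r = max(int(round(width)), 1)
        i0, j0 = int(py * size), int(px * size)
        ii, jj = np.ogrid[-r : r + 1, -r : r + 1]
        disk = ii ** 2 + jj ** 2 <= r ** 2
        ys, xs = np.nonzero(disk)
        ys, xs = ys + i0 - r, xs + j0 - r
        ok = (ys >= 0) & (ys < size) & (xs >= 0) & (xs < size)
        img[ys[ok], xs[ok]] = _VESSEL

    def grow(px: float, py: float, angle: float, depth: int, width: float) -> None:
        step = 2.5 / size
        n_steps = rng.integers(6, 14)
        for _ in range(int(n_steps)):
            angle += rng.normal(0.0, 0.25)
            px += step * np.cos(angle)
            py += step * np.sin(angle)
            if not (0.0 <= px < 1.0 and 0.0 <= py < 1.0):
                return
            stamp(px, py, width)
        if depth > 0:
            for dtheta in (-0.6, 0.6):
                grow(px, py, angle + dtheta + rng.normal(0.0, 0.15),
                     depth - 1, max(width * 0.6, 0.5))

    for _ in range(params.vessel_count):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        px = cx + rx * np.cos(theta)
        py = cy + ry * np.sin(theta)
        grow(px, py, theta, depth=2, width=max(size / 48.0, 1.0))


def render_fundus(params: FundusSceneParams) -> np.ndarray:
    """Render one scene to an (H, W, 3) float64 array in [0, 1].

    Layer order: dark background, reddish eyeball disc, optional PPA annulus,
    optic disc, cup, vessels; then haze (Gaussian blur + brightness washout
    scaled by ``haze_level``) and additive Gaussian pixel noise, clipped.
    Bit-identical output for identical parameters.
    """
    size = params.image_size
    img = np.empty((size, size, 3))
    img[:] = _BACKGROUND

    eyeball = _ellipse_mask(size, (0.5, 0.5), (0.48, 0.48))
    x, y = _pixel_grid(size)
    # mild radial shading so the eyeball is not a flat disk
    rad = np.sqrt((x - 0.5) ** 2 + (y - 0.5) ** 2) / 0.48
    shade = (1.0 - 0.35 * np.clip(rad, 0, 1))[..., None]
    img[eyeball] = (_EYEBALL * shade)[eyeball]

    if params.ppa_present:
        rx, ry = params.disc_radii
        ppa = _ellipse_mask(size, params.disc_center, (rx * 1.45, ry * 1.35))
        img[ppa] = _PPA

    disc = _ellipse_mask(size, params.disc_center, params.disc_radii)
    img[disc] = _DISC

    cdr = params.cup_to_disc_ratio
    cup = _ellipse_mask(
        size,
        params.disc_center,
        (params.disc_radii[0] * cdr, params.disc_radii[1] * cdr),
    )
    img[cup] = _CUP

    if params.vessel_count > 0:
        _draw_vessels(img, params)

    h = params.haze_level
    if h > 0:
        sigma = h * size / 16.0
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
        img = (1.0 - 0.75 * h) * img + 0.75 * h * _HAZE_TINT

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sd, img.shape)

    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Labels and masks
# ---------------------------------------------------------------------------


def glaucoma_label(params: FundusSceneParams) -> int:
    """1 iff CDR strictly exceeds the 0.5 warning threshold."""
    return int(params.cup_to_disc_ratio > GLAUCOMA_CDR_THRESHOLD)


def cataract_label(params: FundusSceneParams,
                   bin_edges: tuple[float, ...] = CATARACT_BIN_EDGES) -> int:
    """Cataract grade 0..len(bin_edges) by haze-level bin membership."""
    h = params.haze_level
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"haze_level must lie in [0,1], got {h}")
    return int(np.searchsorted(bin_edges, h, side="right"))


def pathology_mask(params: FundusSceneParams) -> np.ndarray:
    """Boolean mask of the optic-disc ellipse (the glaucoma-relevant region)."""
    return _ellipse_mask(params.image_size, params.disc_center, params.disc_radii)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _sample_scene(rng: np.random.Generator, image_size: int, cdr: float,
                  haze: float, seed: int) -> FundusSceneParams:
    rx = rng.uniform(0.10, 0.15)
    ry = rx * rng.uniform(1.10, 1.35)
    cx = rng.uniform(0.40, 0.60)
    cy = rng.uniform(0.40, 0.60)
    glaucomatous = cdr > GLAUCOMA_CDR_THRESHOLD
    ppa = bool(rng.random() < (0.5 if glaucomatous else 0.15))
    return FundusSceneParams(
        image_size=image_size,
        disc_center=(cx, cy),
        disc_radii=(rx, ry),
        cup_to_disc_ratio=cdr,
        vessel_count=int(rng.integers(4, 8)),
        vessel_seed=int(rng.integers(0, 2**31 - 1)),
        haze_level=haze,
        ppa_present=ppa,
        noise_sd=0.02,
        seed=seed,
    )


def _class_ranges(task: str, cdr_range: tuple[float, float],
                  haze_range: tuple[float, float]) -> list[tuple[float, float]]:
    """Sampling interval of the label-driving variable for each class."""
    if task == TARGET_TASK:
        lo, hi = cdr_range
        thr = GLAUCOMA_CDR_THRESHOLD
        ranges = [(lo, min(hi, thr)), (max(lo, thr + 1e-6), hi)]
    else:
        lo, hi = haze_range
        edges = [lo, *(min(max(e, lo), hi) for e in CATARACT_BIN_EDGES), hi]
        ranges = list(zip(edges[:-1], edges[1:]))
    for lo_c, hi_c in ranges:
        if hi_c <= lo_c:
            raise ValueError(
                f"empty sampling range ({lo_c:.3g}, {hi_c:.3g}) for a requested class"
            )
    return ranges


def generate_dataset(
    n: int,
    task: str,
    *,
    cdr_range: tuple[float, float] = (0.15, 0.9),
    haze_range: tuple[float, float] = (0.0, 1.0),
    balance: tuple[float, ...] | None = None,
    seed: int = 0,
    image_size: int = 64,
    out_dir: str | Path | None = None,
) -> LabeledDataset:
    """Generate ``n`` labelled scenes for the cataract or glaucoma task.

    Classes are balanced by default (proportions rounded to integers, the
    remainder going to the earliest classes).  Target-task scenes are drawn
    haze-free; source-task scenes span the full CDR range so that cataract
    grade is the only systematic signal.  With ``out_dir`` set, 8-bit PNGs
    and a ``manifest.csv`` (``path,label,task,cdr,haze,seed``) are written.
    """
    if task not in N_CLASSES:
        raise ValueError(f"unknown task {task!r}")
    k = N_CLASSES[task]
    if balance is None:
        balance = (1.0 / k,) * k
    if len(balance) != k:
        raise ValueError(f"balance needs {k} proportions for task {task}")
    if n < sum(1 for b in balance if b > 0):
        raise ValueError("n smaller than the number of requested classes")

    counts = np.floor(np.asarray(balance) / sum(balance) * n).astype(int)
    for i in range(n - counts.sum()):
        counts[i % k] += 1

    ranges = _class_ranges(task, cdr_range, haze_range)
    rng = np.random.default_rng(seed)
    images, labels, rows, scene_params = [], [], [], []
    idx = 0
    for cls, cnt in enumerate(counts):
        lo, hi = ranges[cls]
        for _ in range(cnt):
            v = rng.uniform(lo, hi)
            cdr = v if task == TARGET_TASK else rng.uniform(*_safe_cdr(cdr_range))
            haze = 0.0 if task == TARGET_TASK else v
            scene_seed = int(rng.integers(0, 2**31 - 1))
            params = _sample_scene(rng, image_size, cdr, haze, scene_seed)
            img = render_fundus(params)
            label = glaucoma_label(params) if task == TARGET_TASK else cataract_label(params)
            images.append(img)
            labels.append(label)
            scene_params.append(params)
            rows.append(
                {
                    "path": f"img_{idx:05d}.png",
                    "label": label,
                    "task": task,
                    "cdr": params.cup_to_disc_ratio,
                    "haze": params.haze_level,
                    "seed": params.seed,
                }
            )
            idx += 1

    manifest = pd.DataFrame(rows, columns=["path", "label", "task", "cdr", "haze", "seed"])
    # interleave classes so contiguous minibatch slices stay mixed
    order = _interleave_order(counts)
    images = [images[i] for i in order]
    labels = [labels[i] for i in order]
    scene_params = [scene_params[i] for i in order]
    manifest = manifest.iloc[order].reset_index(drop=True)
    manifest["path"] = [f"img_{i:05d}.png" for i in range(n)]

    ds = LabeledDataset(images=images, labels=np.asarray(labels), task=task,
                        manifest=manifest, scene_params=scene_params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p, img in zip(manifest["path"], images):
            Image.fromarray((img * 255).round().astype(np.uint8)).save(out / p)
        manifest.to_csv(out / "manifest.csv", index=False)
    return ds


def _safe_cdr(cdr_range: tuple[float, float]) -> tuple[float, float]:
    lo, hi = cdr_range
    return max(lo, 0.1), min(hi, 0.95)


def _interleave_order(counts: np.ndarray) -> np.ndarray:
    """Round-robin interleaving of per-class blocks of sizes ``counts``."""
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    order = []
    offsets = np.zeros_like(counts)
    while (offsets < counts).any():
        for cls in range(len(counts)):
            if offsets[cls] < counts[cls]:
                order.append(starts[cls] + offsets[cls])
                offsets[cls] += 1
    return np.asarray(order, dtype=int)
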