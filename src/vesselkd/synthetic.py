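"""Synthetic vascular phantoms with width-partitioned ground truth.

Scenes are recursive random-walk vessel trees drawn on a textured background
(smoothed noise plus a radial illumination falloff).  Each branch carries a
constant calibre drawn from either a thin or a thick width regime, and the
ground truth is decomposed into thin/thick masks by a skeleton +
distance-transform width classifier, standing in for manual thin/thick
annotation of real datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.morphology import skeletonize

__all__ = [
    "SyntheticSceneParams",
    "SampleTriplet",
    "generate_scene",
    "decompose_by_width",
    "make_dataset",
    "DEFAULT_WIDTH_THRESHOLD",
]

DEFAULT_WIDTH_THRESHOLD = 2.0


@dataclass(frozen=True)
class SyntheticSceneParams:
    image_height: int = 64
    image_width: int = 64
    n_trees: int = 2
    thin_width_range: tuple[float, float] = (1.0, 2.0)
    thick_width_range: tuple[float, float] = (3.0, 8.0)
    branch_depth: int = 3
    vessel_contrast: float = 0.6
    background_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image dimensions must be >= 32 in each axis")
        for name, (lo, hi) in (
            ("thin_width_range", self.thin_width_range),
            ("thick_width_range", self.thick_width_range),
        ):
            if lo > hi or lo <= 0:
                raise ValueError(f"degenerate {name}: {(lo, hi)}")
        if self.thin_width_range[1] >= self.thick_width_range[0]:
            raise ValueError("thin and thick width regimes must be disjoint")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.branch_depth < 1:
            raise ValueError("branch_depth must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thin_width_range"] = list(self.thin_width_range)
        d["thick_width_range"] = list(self.thick_width_range)
        return d


@dataclass(frozen=True)
class SampleTriplet:
    image: np.ndarray
    gt: np.ndarray
    thin: np.ndarray
    thick: np.ndarray


def _stamp_path(mask: np.ndarray, points: np.ndarray, width: float) -> None:
    """Paint disks of diameter `width` along a polyline onto a boolean mask."""
    h, w = mask.shape
    radius = width / 2.0
    r_int = int(math.ceil(radius))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = yy * yy + xx * xx <= radius * radius
    for cy, cx in points:
        cy, cx = int(round(cy)), int(round(cx))
        y0, y1 = cy - r_int, cy + r_int + 1
        x0, x1 = cx - r_int, cx + r_int + 1
        sy0, sy1 = max(0, -y0), disk.shape[0] - max(0, y1 - h)
        sx0, sx1 = max(0, -x0), disk.shape[1] - max(0, x1 - w)
        if sy1 <= sy0 or sx1 <= sx0:
            continue
        mask[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] |= disk[sy0:sy1, sx0:sx1]


def _walk(rng: np.random.Generator, start: np.ndarray, angle: float, length: float,
          bounds: tuple[int, int], wobble: float = 0.25) -> np.ndarray:
    """Random-walk polyline: unit steps with jittered heading, clipped to bounds."""
    h, w = bounds
    points = [start.copy()]
    pos = start.astype(float).copy()
    for _ in range(int(length)):
        angle += rng.normal(0.0, wobble)
        pos += np.array([math.sin(angle), math.cos(angle)])
        pos[0] = min(max(pos[0], 0.0), h - 1.0)
        pos[1] = min(max(pos[1], 0.0), w - 1.0)
        points.append(pos.copy())
    return np.array(points)


def _draw_branch(rng, mask, start, angle, depth, params: SyntheticSceneParams):
    """Draw one branch and recurse; root level is thick, leaves are thin."""
    h, w = mask.shape
    scale = min(h, w)
    if depth == 0:
        width = rng.uniform(*params.thick_width_range)
        length = scale * rng.uniform(0.35, 0.55)
    elif depth >= params.branch_depth - 1:
        width = rng.uniform(*params.thin_width_range)
        length = scale * rng.uniform(0.15, 0.30)
    else:
        regime = params.thick_width_range if rng.random() < 0.5 else params.thin_width_range
        width = rng.uniform(*regime)
        length = scale * rng.uniform(0.20, 0.40)
    path = _walk(rng, start, angle, length, (h, w))
    _stamp_path(mask, path, width)
    if depth + 1 >= params.branch_depth:
        return
    n_children = int(rng.integers(1, 3))
    for _ in range(n_children):
        idx = int(rng.integers(len(path) // 2, len(path)))
        child_angle = angle + rng.uniform(0.4, 1.1) * (1 if rng.random() < 0.5 else -1)
        _draw_branch(rng, mask, path[idx], child_angle, depth + 1, params)


def _background(rng, shape: tuple[int, int], noise_sd: float) -> np.ndarray:
    """Smoothed noise plus a radial illumination falloff (fundus-like vignette)."""
    h, w = shape
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=4.0)
    texture = 0.05 * texture / max(texture.std(), 1e-9)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    vignette = 0.75 - 0.15 * r2
    return vignette + texture + rng.normal(0.0, noise_sd, size=shape)


def generate_scene(params: SyntheticSceneParams) -> SampleTriplet:
    """Deterministically render one phantom triplet for `params.seed`."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    gt = np.zeros((h, w), dtype=bool)
    for _ in range(params.n_trees):
        edge = int(rng.integers(0, 4))
        if edge == 0:
            start = np.array([0.0, rng.uniform(0.1, 0.9) * w])
            angle = rng.uniform(0.2, math.pi - 0.2)
        elif edge == 1:
            start = np.array([h - 1.0, rng.uniform(0.1, 0.9) * w])
            angle = rng.uniform(-math.pi + 0.2, -0.2)
        elif edge == 2:
            start = np.array([rng.uniform(0.1, 0.9) * h, 0.0])
            angle = rng.uniform(-math.pi / 2 + 0.2, math.pi / 2 - 0.2)
        else:
            start = np.array([rng.uniform(0.1, 0.9) * h, w - 1.0])
            angle = rng.uniform(math.pi / 2 + 0.2, 3 * math.pi / 2 - 0.2)
        _draw_branch(rng, gt, start, angle, 0, params)
    image = _background(rng, (h, w), params.background_noise_sd)
    image = image - params.vessel_contrast * gt  # vessels darker than surroundings
    image = np.clip(image, 0.0, 1.0)
    gt_u8 = gt.astype(np.uint8)
    thin, thick = decompose_by_width(gt_u8, DEFAULT_WIDTH_THRESHOLD)
    return SampleTriplet(image=image.astype(np.float64), gt=gt_u8, thin=thin, thick=thick)


def decompose_by_width(gt: np.ndarray, width_threshold: float = DEFAULT_WIDTH_THRESHOLD):
    """Partition a binary mask into (thin, thick) by local vessel width.

    The mask is skeletonized; each skeleton pixel's full width is estimated as
    twice its Euclidean distance-transform radius and classed thin when
    <= `width_threshold`.  Every foreground pixel takes the class of its
    nearest skeleton pixel, with ties going to thick.
    """
    gt = np.asarray(gt)
    if not np.isin(gt, (0, 1)).all():
        raise ValueError("gt must be binary (0/1)")
    if width_threshold <= 0:
        raise ValueError("width_threshold must be > 0")
    fg = gt.astype(bool)
    empty = np.zeros_like(gt, dtype=np.uint8)
    if not fg.any():
        return empty.copy(), empty.copy()
    skel = skeletonize(fg)
    if not skel.any():  # pathological tiny regions: treat everything as thin
        return gt.astype(np.uint8), empty.copy()
    radius = distance_transform_edt(fg)
    thin_skel = skel & (2.0 * radius <= width_threshold)
    thick_skel = skel & ~thin_skel
    if not thin_skel.any():
        return empty.copy(), gt.astype(np.uint8)
    if not thick_skel.any():
        return gt.astype(np.uint8), empty.copy()
    d_thin = distance_transform_edt(~thin_skel)
    d_thick = distance_transform_edt(~thick_skel)
    thin = (fg & (d_thin < d_thick)).astype(np.uint8)  # ties -> thick
    thick = (fg & ~thin.astype(bool)).astype(np.uint8)
    return thin, thick


def _write_png(path: Path, array: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, array)


def make_dataset(n_train: int, n_val: int, n_test: int,
                 params: SyntheticSceneParams, root: str | Path) -> Path:
    """Write train/val/test phantom triplets in the standard directory layout.

    Layout: `<root>/<split>/{images,gt,thin,thick}/NNN.png` plus a
    `manifest.yaml` recording the parameters and per-sample seeds.  Splits are
    disjoint by construction: sample i of split s uses seed
    `params.seed + offset(s) + i` with non-overlapping offsets.
    """
    for name, n in (("n_train", n_train), ("n_val", n_val), ("n_test", n_test)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    root = Path(root)
    splits = {"train": n_train, "val": n_val, "test": n_test}
    offsets = {"train": 0, "val": 100_000, "test": 200_000}
    manifest = {"params": params.to_dict(), "splits": {}}
    for split, count in splits.items():
        for sub in ("images", "gt", "thin", "thick"):
            (root / split / sub).mkdir(parents=True, exist_ok=True)
        seeds = []
        for i in range(count):
            seed = params.seed + offsets[split] + i
            seeds.append(seed)
            sample = generate_scene(
                SyntheticSceneParams(**{**params.to_dict(), "seed": seed})
            )
            name = f"{i:03d}.png"
            _write_png(root / split / "images" / name,
                       np.round(sample.image * 255.0).astype(np.uint8))
            for sub, mask in (("gt", sample.gt), ("thin", sample.thin), ("thick", sample.thick)):
                _write_png(root / split / sub / name, (mask * 255).astype(np.uint8))
        manifest["splits"][split] = {"count": count, "seeds": seeds}
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return root
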