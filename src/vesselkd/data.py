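"""Dataset loading for the on-disk layout `<root>/<split>/{images,gt,thin,thick}/`.

Images may be PNG/TIFF/GIF/PGM, grayscale or RGB; masks are binary rasters
(any nonzero pixel is foreground).  Known benchmark names carry their
published train/val/test split conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Sample", "SplitData", "VesselDataset", "load_dataset", "KNOWN_SPLITS"]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".gif", ".pgm")

# (n_train, n_val, n_test) conventions for the published benchmarks: files are
# ordered by name and assigned train -> val -> test.
KNOWN_SPLITS: dict[str, tuple[int, int, int]] = {
    "drive": (18, 2, 20),
    "chasedb1": (18, 2, 8),
    "chuac": (16, 4, 10),
    "dca1": (80, 20, 34),
}


@dataclass
class Sample:
    name: str
    image: np.ndarray  # (C, H, W) float in [0, 1]
    gt: np.ndarray     # (H, W) uint8 {0, 1}
    thin: np.ndarray | None = None
    thick: np.ndarray | None = None

    def mask_for_role(self, role: str) -> np.ndarray:
        if role == "original":
            return self.gt
        mask = getattr(self, role, None)
        if mask is None:
            raise ValueError(f"sample {self.name!r} has no {role!r} mask")
        return mask


@dataclass
class SplitData:
    samples: list[Sample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def pairs(self, role: str = "original"):
        return [(s.image, s.mask_for_role(role)) for s in self.samples]


@dataclass
class VesselDataset:
    root: Path
    train: SplitData
    val: SplitData
    test: SplitData
    in_channels: int = 1

    def split(self, name: str) -> SplitData:
        return {"train": self.train, "val": self.val, "test": self.test}[name]


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.transpose(2, 0, 1)
    else:
        arr = arr[None, :, :]
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def _read_mask(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def _load_split(split_dir: Path, names: list[str] | None = None) -> SplitData:
    images_dir = split_dir / "images"
    if not images_dir.is_dir():
        return SplitData()
    files = sorted(
        p for p in images_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if names is not None:
        files = [p for p in files if p.name in set(names)]
    samples = []
    for img_path in files:
        gt_path = _matching_mask(split_dir / "gt", img_path)
        if gt_path is None:
            raise FileNotFoundError(
                f"missing ground-truth mask for {img_path.name} in {split_dir / 'gt'}"
            )
        image = _read_image(img_path)
        gt = _read_mask(gt_path)
        if image.shape[-2:] != gt.shape:
            raise ValueError(
                f"image/mask shape mismatch for {img_path.name}: "
                f"{image.shape[-2:]} vs {gt.shape}"
            )
        sample = Sample(name=img_path.stem, image=image, gt=gt)
        for role in ("thin", "thick"):
            mask_path = _matching_mask(split_dir / role, img_path)
            if mask_path is not None:
                setattr(sample, role, _read_mask(mask_path))
        samples.append(sample)
    return SplitData(samples)


def _matching_mask(mask_dir: Path, img_path: Path) -> Path | None:
    if not mask_dir.is_dir():
        return None
    for ext in IMAGE_EXTENSIONS:
        candidate = mask_dir / (img_path.stem + ext)
        if candidate.exists():
            return candidate
    return None


def load_dataset(root: str | Path, name: str | None = None) -> VesselDataset:
    """Load a dataset laid out as `<root>/<split>/{images,gt,thin,thick}/`.

    With per-split directories present (the synthetic layout) splits load
    directly.  For a known benchmark `name` with a flat `<root>/{images,gt,...}`
    layout, the published ordered train/val/test counts are applied instead.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    if (root / "train").is_dir() or (root / "val").is_dir() or (root / "test").is_dir():
        train = _load_split(root / "train")
        val = _load_split(root / "val")
        test = _load_split(root / "test")
    elif name is not None and name.lower() in KNOWN_SPLITS:
        n_train, n_val, n_test = KNOWN_SPLITS[name.lower()]
        flat = _load_split(root)
        expected = n_train + n_val + n_test
        if len(flat) < expected:
            raise ValueError(
                f"{name} layout expects {expected} images, found {len(flat)}"
            )
        train = SplitData(flat.samples[:n_train])
        val = SplitData(flat.samples[n_train : n_train + n_val])
        test = SplitData(flat.samples[n_train + n_val : expected])
    else:
        raise ValueError(
            f"no train/val/test directories under {root} and no known dataset name given"
        )
    channels = {s.image.shape[0] for split in (train, val, test) for s in split}
    in_channels = channels.pop() if len(channels) == 1 else 1
    return VesselDataset(root=root, train=train, val=val, test=test, in_channels=in_channels)
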