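"""Pixel-wise evaluation: confusion counts and ACC/SEN/SPE/F1/IoU.

Confusion counts are micro-aggregated (pooled over every evaluated pixel of
every image); undefined ratios are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import pad_to_spec, unpad

__all__ = [
    "ConfusionCounts",
    "binarize",
    "confusion",
    "compute_metrics",
    "evaluate_set",
    "METRIC_NAMES",
]

METRIC_NAMES = ("ACC", "SEN", "SPE", "F1", "IOU")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities; ties (p == threshold) go to foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(p) >= threshold).astype(np.uint8)


def _require_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion with vessel (1) as the positive class."""
    p = _require_binary(pred, "pred")
    g = _require_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fp=int((p & ~g).sum()),
        tn=int((~p & ~g).sum()),
        fn=int((~p & g).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    return {
        "ACC": _ratio(c.tp + c.tn, c.total),
        "SEN": _ratio(c.tp, c.tp + c.fn),
        "SPE": _ratio(c.tn, c.tn + c.fp),
        "F1": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        "IOU": _ratio(c.tp, c.tp + c.fp + c.fn),
    }


def predict_probs(model, image: np.ndarray, spec="auto16") -> np.ndarray:
    """Pad, run the network in eval mode, unpad, return sigmoid probabilities."""
    padded, used_spec = pad_to_spec(image, spec)
    if padded.ndim == 2:
        padded = padded[None, :, :]
    model.eval()
    logits = model(padded[None, ...])
    probs = 1.0 / (1.0 + np.exp(-logits.data[0, 0]))
    return unpad(probs, used_spec)


def evaluate_set(model, samples, spec="auto16", threshold: float = 0.5):
    """Micro-aggregated metrics over (image, gt) pairs.

    Returns (summary_row, per_image_rows); all values are fractions in [0, 1].
    """
    samples = list(samples)
    if not samples:
        raise ValueError("evaluate_set needs a non-empty split")
    total = ConfusionCounts(0, 0, 0, 0)
    per_image = []
    for i, (image, gt) in enumerate(samples):
        probs = predict_probs(model, image, spec)
        pred = binarize(probs, threshold)
        c = confusion(pred, gt)
        total = total + c
        per_image.append({"index": i, **compute_metrics(c)})
    return compute_metrics(total), per_image


def to_percent(row: dict[str, float]) -> dict[str, float]:
    """Reporting convention: fractions -> percent at 2 decimals."""
    return {k: round(v * 100.0, 2) if isinstance(v, float) else v for k, v in row.items()}
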