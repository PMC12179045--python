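"""Hard-label segmentation losses.

All losses consume per-pixel probabilities (post-sigmoid) together with a
binary target and return a scalar; inputs may be numpy arrays or autodiff
tensors, so the same definitions serve both unit tests and training.
Probabilities entering a logarithm are epsilon-clamped first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import Tensor, as_tensor

__all__ = [
    "LossConfig",
    "LOSS_NAMES",
    "bce_loss",
    "dice_loss",
    "soft_dice_loss",
    "tversky_loss",
    "focal_loss",
    "focal_tversky_loss",
    "dice_bce_loss",
    "combined_loss",
    "combo_loss",
    "make_loss",
]

_EPS = 1e-7

LOSS_NAMES = (
    "DiceLoss",
    "CombinedLoss",
    "TverskyLoss",
    "ComboLoss",
    "SoftDiceLoss",
    "DiceBCELoss",
    "FocalLoss",
    "FocalTverskyLoss",
    "BCE",
)


@dataclass(frozen=True)
class LossConfig:
    name: str = "DiceBCELoss"
    smooth: float = 1.0
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    focal_gamma: float = 2.0
    focal_tversky_gamma: float = 0.75
    combo_weight: float = 0.5

    def __post_init__(self):
        if self.name not in LOSS_NAMES:
            raise ValueError(
                f"unknown loss {self.name!r}; valid names: {', '.join(LOSS_NAMES)}"
            )
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")
        if self.tversky_alpha + self.tversky_beta <= 0:
            raise ValueError("tversky_alpha + tversky_beta must be > 0")
        if self.focal_gamma < 0 or self.focal_tversky_gamma < 0:
            raise ValueError("gammas must be >= 0")
        if not 0.0 <= self.combo_weight <= 1.0:
            raise ValueError("combo_weight must be in [0, 1]")


def _check_shapes(p: Tensor, y: Tensor) -> None:
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {y.shape}")


def bce_loss(p, y, eps: float = _EPS) -> Tensor:
    """Mean binary cross-entropy, natural log, epsilon-clamped probabilities."""
    p, y = as_tensor(p), as_tensor(y)
    _check_shapes(p, y)
    pc = p.clamp(eps, 1.0 - eps)
    return -(y * pc.log() + (1.0 - y) * (1.0 - pc).log()).mean()


def dice_loss(p, y, smooth: float = 1.0) -> Tensor:
    p, y = as_tensor(p), as_tensor(y)
    _check_shapes(p, y)
    inter = (p * y).sum()
    return 1.0 - (2.0 * inter + smooth) / (p.sum() + y.sum() + smooth)


def soft_dice_loss(p, y, smooth: float = 1.0) -> Tensor:
    """Dice with squared terms in the denominator."""
    p, y = as_tensor(p), as_tensor(y)
    _check_shapes(p, y)
    inter = (p * y).sum()
    return 1.0 - (2.0 * inter + smooth) / ((p**2).sum() + (y**2).sum() + smooth)


def _tversky_index(p: Tensor, y: Tensor, alpha: float, beta: float, smooth: float) -> Tensor:
    tp = (p * y).sum()
    fp = (p * (1.0 - y)).sum()
    fn = ((1.0 - p) * y).sum()
    return (tp + smooth) / (tp + alpha * fp + beta * fn + smooth)


def tversky_loss(p, y, alpha: float = 0.7, beta: float = 0.3, smooth: float = 1.0) -> Tensor:
    p, y = as_tensor(p), as_tensor(y)
    _check_shapes(p, y)
    return 1.0 - _tversky_index(p, y, alpha, beta, smooth)


def focal_loss(p, y, gamma: float = 2.0, eps: float = _EPS) -> Tensor:
    """Focal BCE without class-balancing alpha; gamma=0 reduces to BCE."""
    p, y = as_tensor(p), as_tensor(y)
    _check_shapes(p, y)
    pc = p.clamp(eps, 1.0 - eps)
    pos = y * (1.0 - pc) ** gamma * pc.log()
    neg = (1.0 - y) * pc**gamma * (1.0 - pc).log()
    return -(pos + neg).mean()


def focal_tversky_loss(p, y, alpha: float = 0.7, beta: float = 0.3,
                       gamma: float = 0.75, smooth: float = 1.0) -> Tensor:
    p, y = as_tensor(p), as_tensor(y)
    _check_shapes(p, y)
    return (1.0 - _tversky_index(p, y, alpha, beta, smooth)) ** gamma


def dice_bce_loss(p, y, smooth: float = 1.0, eps: float = _EPS) -> Tensor:
    return dice_loss(p, y, smooth) + bce_loss(p, y, eps)


def combined_loss(p, y, smooth: float = 1.0, eps: float = _EPS) -> Tensor:
    """Unit-weight BCE + Dice (kept distinct from the weighted ComboLoss)."""
    return bce_loss(p, y, eps) + dice_loss(p, y, smooth)


def combo_loss(p, y, weight: float = 0.5, smooth: float = 1.0, eps: float = _EPS) -> Tensor:
    return weight * bce_loss(p, y, eps) + (1.0 - weight) * dice_loss(p, y, smooth)


def make_loss(config: LossConfig):
    """Return a `(probabilities, target) -> scalar` callable for the config."""
    c = config
    dispatch = {
        "BCE": lambda p, y: bce_loss(p, y),
        "DiceLoss": lambda p, y: dice_loss(p, y, c.smooth),
        "SoftDiceLoss": lambda p, y: soft_dice_loss(p, y, c.smooth),
        "TverskyLoss": lambda p, y: tversky_loss(p, y, c.tversky_alpha, c.tversky_beta, c.smooth),
        "FocalLoss": lambda p, y: focal_loss(p, y, c.focal_gamma),
        "FocalTverskyLoss": lambda p, y: focal_tversky_loss(
            p, y, c.tversky_alpha, c.tversky_beta, c.focal_tversky_gamma, c.smooth
        ),
        "DiceBCELoss": lambda p, y: dice_bce_loss(p, y, c.smooth),
        "CombinedLoss": lambda p, y: combined_loss(p, y, c.smooth),
        "ComboLoss": lambda p, y: combo_loss(p, y, c.combo_weight, c.smooth),
    }
    return dispatch[config.name]
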