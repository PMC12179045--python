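"""U-Net construction, analytic parameter/MAC accounting, and input padding.

The network is the classic encoder-decoder U-Net: two same-padded 3x3
convolutions per block (batch norm before ReLU), 2x2 max-pool downsampling,
2x2 stride-2 transposed-convolution upsampling with skip concatenation and a
final 1x1 convolution emitting logits.  ``count_parameters`` and
``count_macs`` walk the same layer schedule analytically, so they can be
cross-checked against an instantiated network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Literal

import numpy as np

from . import nn

__all__ = [
    "UNetConfig",
    "PaddingSpec",
    "UNet",
    "build_unet",
    "count_parameters",
    "count_macs",
    "parameter_size_mb",
    "pad_to_spec",
    "unpad",
    "padding_for_dataset",
    "DATASET_PADDING",
    "accounting_report",
]


@dataclass(frozen=True)
class UNetConfig:
    """Channel-schedule description of a U-Net.

    Channel width at encoder level ``i`` is ``base_width * 2**i // width_divisor``;
    the standard network is ``base_width=64, depth=4, width_divisor=1`` and the
    Lite variant divides every width by 8.
    """

    in_channels: int = 3
    out_channels: int = 1
    base_width: int = 64
    depth: int = 4
    width_divisor: int = 1
    batch_norm: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.width_divisor < 1:
            raise ValueError("width_divisor must be a positive integer")
        if self.base_width % self.width_divisor != 0:
            raise ValueError(
                f"base_width {self.base_width} not divisible by width_divisor {self.width_divisor}"
            )
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")

    def widths(self) -> list[int]:
        """Encoder widths level 0..depth (the last entry is the bottleneck)."""
        return [self.base_width * 2**i // self.width_divisor for i in range(self.depth + 1)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PaddingSpec:
    pad_bottom: int
    pad_right: int
    target_shape: tuple[int, int]

    def __post_init__(self):
        if self.pad_bottom < 0 or self.pad_right < 0:
            raise ValueError("pads must be non-negative")


# Per-dataset pads used in the published experiments; targets are multiples of 16.
DATASET_PADDING: dict[str, tuple[int, int]] = {
    "drive": (592, 576),      # 584x565 -> pad 8 bottom, 11 right
    "chasedb1": (1008, 1008), # 960x999 -> pad 48 bottom, 9 right
    "dca1": (320, 320),       # 300x300 -> pad 20 bottom, 20 right
    "chuac": (512, 512),      # already aligned, no padding
}


def padding_for_dataset(name: str, shape: tuple[int, int]) -> PaddingSpec:
    target = DATASET_PADDING[name.lower()]
    return PaddingSpec(target[0] - shape[0], target[1] - shape[1], target)


def _auto16(shape: tuple[int, int]) -> PaddingSpec:
    th = -(-shape[0] // 16) * 16
    tw = -(-shape[1] // 16) * 16
    return PaddingSpec(th - shape[0], tw - shape[1], (th, tw))


def pad_to_spec(image: np.ndarray, spec: "PaddingSpec | str" = "auto16"):
    """Zero-pad bottom/right to the spec target; returns (padded, spec).

    Accepts HW or CHW arrays; "auto16" pads each axis to the next multiple of 16.
    """
    h, w = image.shape[-2], image.shape[-1]
    if isinstance(spec, str):
        if spec != "auto16":
            raise ValueError(f"unknown padding spec {spec!r}")
        spec = _auto16((h, w))
    if (h + spec.pad_bottom, w + spec.pad_right) != tuple(spec.target_shape):
        raise ValueError(
            f"padding spec {spec} incompatible with image of shape {(h, w)}"
        )
    pads = [(0, 0)] * (image.ndim - 2) + [(0, spec.pad_bottom), (0, spec.pad_right)]
    return np.pad(image, pads), spec


def unpad(output: np.ndarray, spec: PaddingSpec) -> np.ndarray:
    h = output.shape[-2] - spec.pad_bottom
    w = output.shape[-1] - spec.pad_right
    return output[..., :h, :w]


# ---------------------------------------------------------------------------
# Layer schedule shared by the analytic accounting (the builder constructs the
# same sequence independently from nn modules).
# ---------------------------------------------------------------------------

def _layer_schedule(cfg: UNetConfig) -> Iterator[tuple[str, int, int, int, int]]:
    """Yield (kind, c_in, c_out, kernel, level) for every parameterised layer.

    level is the spatial scale: feature maps at level L have H/2^L x W/2^L pixels.
    """
    w = cfg.widths()
    c = cfg.in_channels
    for lev in range(cfg.depth):
        for _ in range(2):
            yield ("conv", c, w[lev], 3, lev)
            if cfg.batch_norm:
                yield ("bn", w[lev], w[lev], 0, lev)
            c = w[lev]
    for _ in range(2):
        yield ("conv", c, w[cfg.depth], 3, cfg.depth)
        if cfg.batch_norm:
            yield ("bn", w[cfg.depth], w[cfg.depth], 0, cfg.depth)
        c = w[cfg.depth]
    for lev in range(cfg.depth - 1, -1, -1):
        yield ("tconv", c, w[lev], 2, lev)
        c = 2 * w[lev]  # skip concatenation
        for _ in range(2):
            yield ("conv", c, w[lev], 3, lev)
            if cfg.batch_norm:
                yield ("bn", w[lev], w[lev], 0, lev)
            c = w[lev]
    yield ("conv", c, cfg.out_channels, 1, 0)


def count_parameters(cfg: UNetConfig) -> int:
    """Closed-form parameter total (conv/tconv weights+biases, BN scale+shift)."""
    total = 0
    for kind, cin, cout, k, _ in _layer_schedule(cfg):
        if kind in ("conv", "tconv"):
            total += k * k * cin * cout + cout
        elif kind == "bn":
            total += 2 * cout
    return total


def count_macs(cfg: UNetConfig, input_shape: tuple[int, int]) -> int:
    """Multiply-accumulate total for one forward pass at `input_shape`.

    Counts convolution and transposed-convolution layers only, as
    out_H * out_W * C_in * C_out * k^2; pooling, BN and activations excluded.
    """
    h, w = input_shape
    if h % 2**cfg.depth or w % 2**cfg.depth:
        raise ValueError(
            f"input {input_shape} not divisible by 2^depth={2**cfg.depth}; pad first"
        )
    total = 0
    for kind, cin, cout, k, lev in _layer_schedule(cfg):
        if kind == "bn":
            continue
        oh, ow = h // 2**lev, w // 2**lev
        total += oh * ow * cin * cout * k * k
    return total


def parameter_size_mb(param_count: int, bytes_per_param: int = 4) -> float:
    """Size in MB (10^6 bytes) of float32 weights, rounded to 2 decimals."""
    if param_count < 0:
        raise ValueError("param_count must be >= 0")
    return round(param_count * bytes_per_param / 1e6, 2)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class _ConvBlock(nn.Module):
    def __init__(self, cin: int, cout: int, batch_norm: bool, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, padding=1)
        self.bn1 = nn.BatchNorm2d(cout) if batch_norm else None
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm2d(cout) if batch_norm else None

    def forward(self, x):
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = x.relu()
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return x.relu()


class UNet(nn.Module):
    def __init__(self, config: UNetConfig, rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.config = config
        w = config.widths()
        self.encoders = [
            _ConvBlock(config.in_channels if i == 0 else w[i - 1], w[i], config.batch_norm, rng)
            for i in range(config.depth)
        ]
        self.pool = nn.MaxPool2d()
        self.bottleneck = _ConvBlock(
            w[config.depth - 1], w[config.depth], config.batch_norm, rng
        )
        self.upconvs = [
            nn.ConvTranspose2d(w[i + 1], w[i], rng) for i in range(config.depth - 1, -1, -1)
        ]
        self.decoders = [
            _ConvBlock(2 * w[i], w[i], config.batch_norm, rng)
            for i in range(config.depth - 1, -1, -1)
        ]
        self.head = nn.Conv2d(w[0], config.out_channels, 1, rng)

    def forward(self, x):
        x = nn.as_tensor(x)
        h, w = x.shape[-2], x.shape[-1]
        div = 2**self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={div}; "
                "use pad_to_spec to align the image first"
            )
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.upconvs, self.decoders, reversed(skips)):
            x = up(x)
            x = nn.concat_channels([skip, x])
            x = dec(x)
        return self.head(x)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Instantiate a U-Net with seeded Kaiming-normal initialisation."""
    return UNet(config, np.random.default_rng(seed))


def accounting_report(configs: dict[str, UNetConfig], input_shape: tuple[int, int]):
    """Params (M), MACs (G) at `input_shape`, and parameter size (MB) per model."""
    import pandas as pd

    rows = []
    for name, cfg in configs.items():
        p = count_parameters(cfg)
        rows.append(
            {
                "Model": name,
                "#Params (M)": round(p / 1e6, 3),
                "#Flops (G)": round(count_macs(cfg, input_shape) / 1e9, 2),
                "Parameter Size (MB)": parameter_size_mb(p),
            }
        )
    return pd.DataFrame(rows)
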