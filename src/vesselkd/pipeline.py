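"""Training: supervised teachers, multi-teacher distillation, sweeps.

Checkpoint discipline follows the experimental protocol: Adam, no early
stopping, no augmentation, best model selected by validation loss after
every epoch.  All randomness flows through ``TrainConfig.seed`` so runs are
bit-reproducible.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, replace, field
from pathlib import Path

import numpy as np

from . import nn
from .data import VesselDataset, SplitData
from .distill import DistillationConfig, avg_distillation_loss, distillation_loss, total_student_loss
from .losses import LossConfig, make_loss
from .metrics import evaluate_set
from .models import UNet, UNetConfig, build_unet, pad_to_spec

__all__ = [
    "TrainConfig",
    "TeacherSpec",
    "train_teacher",
    "train_student",
    "run_sweep",
    "save_checkpoint",
    "load_checkpoint",
    "multi_teacher_benchmark",
]

TEACHER_ROLES = ("original", "thick", "thin")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 250
    seed: int = 0
    device: str = "cpu"
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TeacherSpec:
    role: str
    config: UNetConfig
    checkpoint: Path | None = None
    model: UNet | None = None

    def load(self) -> UNet:
        if self.model is None:
            if self.checkpoint is None:
                raise ValueError(f"teacher {self.role!r} has neither model nor checkpoint")
            self.model, _ = load_checkpoint(self.checkpoint)
        return self.model


# ---------------------------------------------------------------------------
# Checkpoints: weights + config metadata in one npz
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: UNet, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    payload = {"config": model.config.to_dict(), "meta": meta or {}}
    state["__meta__"] = np.frombuffer(json.dumps(payload).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    with np.load(Path(path)) as archive:
        state = {k: archive[k] for k in archive.files}
    payload = json.loads(bytes(state.pop("__meta__").tobytes()).decode())
    model = build_unet(UNetConfig(**payload["config"]))
    model.load_state_dict(state)
    model.eval()
    return model, payload.get("meta", {})


# ---------------------------------------------------------------------------
# Core training loop
# ---------------------------------------------------------------------------

def _stack_split(split: SplitData, role: str) -> tuple[np.ndarray, np.ndarray]:
    """Pad every sample to a 16-aligned frame and stack into NCHW / NHW arrays."""
    images, masks = [], []
    for sample in split:
        img, spec = pad_to_spec(sample.image, "auto16")
        mask, _ = pad_to_spec(sample.mask_for_role(role), spec)
        images.append(img)
        masks.append(mask)
    return np.stack(images), np.stack(masks).astype(np.float64)


def _train_loop(model: UNet, step_loss, val_loss_fn, train_n: int, cfg: TrainConfig):
    """Generic loop: permuted mini-batches, per-epoch validation, best-state keep."""
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    best_val = np.inf
    best_state = model.state_dict()
    history = []
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(train_n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, train_n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = step_loss(model, idx)
            loss.backward()
            opt.step()
            epoch_loss += float(loss)
            n_batches += 1
        model.eval()
        val = float(val_loss_fn(model))
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_loss": val}
        )
        if val < best_val:
            best_val = val
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return history


def train_teacher(role: str, dataset: VesselDataset, unet_cfg: UNetConfig,
                  train_cfg: TrainConfig, loss_cfg: LossConfig | None = None,
                  run_dir: str | Path | None = None) -> tuple[TeacherSpec, list[dict]]:
    """Supervised training of one specialist teacher (DiceBCELoss by default)."""
    if role not in TEACHER_ROLES:
        raise ValueError(f"unknown teacher role {role!r}; valid: {TEACHER_ROLES}")
    if len(dataset.train) == 0 or len(dataset.val) == 0:
        raise ValueError("teacher training needs non-empty train and val splits")
    loss_fn = make_loss(loss_cfg or LossConfig("DiceBCELoss"))
    x_train, y_train = _stack_split(dataset.train, role)
    x_val, y_val = _stack_split(dataset.val, role)
    model = build_unet(unet_cfg, seed=train_cfg.seed)

    def step_loss(m, idx):
        probs = m(x_train[idx]).sigmoid()
        return loss_fn(probs, nn.Tensor(y_train[idx][:, None]))

    def val_loss(m):
        return loss_fn(m(x_val).sigmoid(), nn.Tensor(y_val[:, None]))

    history = _train_loop(model, step_loss, val_loss, len(dataset.train), train_cfg)
    spec = TeacherSpec(role=role, config=unet_cfg, model=model)
    if run_dir is not None:
        spec.checkpoint = save_checkpoint(
            Path(run_dir) / f"teacher_{role}.npz", model, {"role": role}
        )
    return spec, history


def train_student(teachers: list[TeacherSpec], dataset: VesselDataset,
                  unet_cfg: UNetConfig, train_cfg: TrainConfig,
                  distill_cfg: DistillationConfig,
                  run_dir: str | Path | None = None) -> tuple[UNet, list[dict]]:
    """Distill frozen teachers into a student per the weighted-total objective.

    Every step computes one KL distillation loss per teacher against the
    student's probabilities, averages them, adds the (optionally penalized)
    hard loss against the original ground truth, and backpropagates the
    weighted total.  Validation uses the same total for checkpoint selection.
    """
    if not teachers:
        raise ValueError(
            "no teachers supplied: train teacher checkpoints first "
            "(pipeline.train_teacher or the train-teacher CLI command)"
        )
    if len(dataset.train) == 0 or len(dataset.val) == 0:
        raise ValueError("student training needs non-empty train and val splits")
    teacher_models = []
    for spec in teachers:
        m = spec.load()
        m.eval()
        if m.config.in_channels != unet_cfg.in_channels:
            raise ValueError(
                f"teacher {spec.role!r} expects {m.config.in_channels} input channels, "
                f"student config has {unet_cfg.in_channels}"
            )
        teacher_models.append(m)
    hard_fn = make_loss(distill_cfg.hard_loss)
    x_train, y_train = _stack_split(dataset.train, "original")
    x_val, y_val = _stack_split(dataset.val, "original")
    # teacher logits are input-only functions of frozen weights: precompute
    t_train = [m(x_train).data for m in teacher_models]
    t_val = [m(x_val).data for m in teacher_models]
    model = build_unet(unet_cfg, seed=train_cfg.seed)

    def total_loss(m, x, y, teacher_logits, idx=None):
        z_s = m(x if idx is None else x[idx])
        probs = z_s.sigmoid()
        target = nn.Tensor((y if idx is None else y[idx])[:, None])
        hard = hard_fn(probs, target)
        per_teacher = [
            distillation_loss(zt if idx is None else zt[idx], z_s, distill_cfg)
            for zt in teacher_logits
        ]
        return total_student_loss(avg_distillation_loss(per_teacher), hard, distill_cfg)

    def step_loss(m, idx):
        return total_loss(m, x_train, y_train, t_train, idx)

    def val_loss(m):
        return total_loss(m, x_val, y_val, t_val)

    history = _train_loop(model, step_loss, val_loss, len(dataset.train), train_cfg)
    if run_dir is not None:
        save_checkpoint(
            Path(run_dir) / "student.npz", model,
            {"teachers": [t.role for t in teachers]},
        )
    return model, history


# ---------------------------------------------------------------------------
# Ablation sweeps
# ---------------------------------------------------------------------------

SWEEP_KINDS = ("temperature", "penalty", "loss", "teachers", "lite")


def run_sweep(kind: str, grid, teachers: list[TeacherSpec], dataset: VesselDataset,
              unet_cfg: UNetConfig, train_cfg: TrainConfig,
              distill_cfg: DistillationConfig):
    """One student training + test evaluation per grid point, shared seeds."""
    import pandas as pd

    if kind not in SWEEP_KINDS:
        raise ValueError(f"unknown sweep kind {kind!r}; valid: {SWEEP_KINDS}")
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for value in grid:
        d_cfg, u_cfg, active = distill_cfg, unet_cfg, teachers
        if kind == "temperature":
            d_cfg = replace(distill_cfg, temperature=float(value))
        elif kind == "penalty":
            d_cfg = replace(distill_cfg, penalty=float(value))
        elif kind == "loss":
            loss_cfg = value if isinstance(value, LossConfig) else LossConfig(str(value))
            d_cfg = replace(distill_cfg, hard_loss=loss_cfg)
        elif kind == "teachers":
            roles = tuple(value)
            active = [t for t in teachers if t.role in roles]
            if len(active) != len(roles):
                missing = set(roles) - {t.role for t in teachers}
                raise ValueError(f"missing teachers for roles {sorted(missing)}")
            d_cfg = replace(distill_cfg, teacher_roles=roles)
        elif kind == "lite":
            u_cfg = replace(unet_cfg, width_divisor=int(value))
        model, _ = train_student(active, dataset, u_cfg, train_cfg, d_cfg)
        summary, _ = evaluate_set(model, dataset.test.pairs("original"))
        rows.append(
            {
                "sweep": kind,
                "value": str(value),
                **{k: round(v * 100.0, 2) for k, v in summary.items()},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged desk-scale benchmark (synthetic data, small U-Nets)
# ---------------------------------------------------------------------------

def default_benchmark_params(seed: int = 0):
    """Easy-regime synthetic scene: high contrast, little noise, 64x64."""
    from .synthetic import SyntheticSceneParams

    return SyntheticSceneParams(
        image_height=64,
        image_width=64,
        n_trees=2,
        branch_depth=3,
        vessel_contrast=0.9,
        background_noise_sd=0.01,
        seed=seed,
    )


def multi_teacher_benchmark(seed: int, work_dir: str | Path, *,
                            n_train: int = 8, n_val: int = 2, n_test: int = 4,
                            epochs: int = 30, single_teacher_runs: bool = True) -> dict:
    """Desk-scale analogue of the teacher-contribution experiment.

    Generates a synthetic dataset, trains the three specialist teachers, then
    distills single-teacher and three-teacher students; returns validation F1
    per teacher and test F1 per student configuration.
    """
    from .data import load_dataset
    from .synthetic import make_dataset

    work_dir = Path(work_dir)
    params = default_benchmark_params(seed=seed * 1_000_003 + 17)
    ds_root = make_dataset(n_train, n_val, n_test, params, work_dir / f"data_seed{seed}")
    dataset = load_dataset(ds_root)
    unet_cfg = UNetConfig(in_channels=1, base_width=16, depth=2)
    train_cfg = TrainConfig(epochs=epochs, seed=seed)
    distill_cfg = DistillationConfig()

    teacher_val_f1 = {}
    teachers = []
    for role in TEACHER_ROLES:
        spec, _ = train_teacher(role, dataset, unet_cfg, train_cfg)
        summary, _ = evaluate_set(spec.model, dataset.val.pairs(role))
        teacher_val_f1[role] = summary["F1"]
        teachers.append(spec)

    student_f1 = {}
    combos = {"multi": TEACHER_ROLES}
    if single_teacher_runs:
        combos.update({f"T{i + 1}+S": (role,) for i, role in enumerate(TEACHER_ROLES)})
    for label, roles in combos.items():
        active = [t for t in teachers if t.role in roles]
        d_cfg = replace(distill_cfg, teacher_roles=tuple(roles))
        model, _ = train_student(active, dataset, unet_cfg, train_cfg, d_cfg)
        summary, _ = evaluate_set(model, dataset.test.pairs("original"))
        student_f1[label] = summary["F1"]
    return {"seed": seed, "teacher_val_f1": teacher_val_f1, "student_f1": student_f1}
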