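"""Response-based multi-teacher distillation mathematics.

Teacher logits are temperature-softened (``sigmoid(z/T)``) while student
logits pass through a plain sigmoid; both probability maps are clamped to
``[eps, 1-eps]`` before the per-pixel binary KL divergence

    KL(p_t || p_s) = p_t*ln(p_t/p_s) + (1-p_t)*ln((1-p_t)/(1-p_s))

is averaged over pixels.  Per-teacher losses are arithmetically averaged and
combined with the hard-label loss as

    total = alpha * avg_distillation + (1 - alpha) * penalty * hard
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .losses import LossConfig
from .nn import Tensor, as_tensor

__all__ = [
    "DistillationConfig",
    "DistillationBreakdown",
    "soften",
    "clamp_probs",
    "kl_binary",
    "distillation_loss",
    "avg_distillation_loss",
    "total_student_loss",
]

TEACHER_ROLES = ("original", "thick", "thin")


@dataclass(frozen=True)
class DistillationConfig:
    temperature: float = 3.0
    alpha: float = 0.5
    epsilon: float = 1e-7
    penalty: float = 1.0
    hard_loss: LossConfig = field(default_factory=LossConfig)
    teacher_roles: tuple[str, ...] = TEACHER_ROLES
    scale_student_logits: bool = False  # escape hatch: classic KD softens both sides

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if self.penalty < 1.0:
            raise ValueError("penalty must be >= 1")
        if not self.teacher_roles:
            raise ValueError("at least one teacher role is required")
        unknown = set(self.teacher_roles) - set(TEACHER_ROLES)
        if unknown:
            raise ValueError(f"unknown teacher roles: {sorted(unknown)}")


@dataclass(frozen=True)
class DistillationBreakdown:
    per_teacher: tuple[float, ...]
    average: float
    hard: float
    total: float


def soften(z, temperature: float, scale: str = "teacher") -> Tensor:
    """Logits -> probabilities; temperature divides teacher logits only."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    z = as_tensor(z)
    if scale == "teacher":
        return (z * (1.0 / temperature)).sigmoid()
    if scale == "student":
        return z.sigmoid()
    raise ValueError(f"scale must be 'teacher' or 'student', got {scale!r}")


def clamp_probs(p, epsilon: float = 1e-7) -> Tensor:
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    return as_tensor(p).clamp(epsilon, 1.0 - epsilon)


def kl_binary(p_teacher, p_student) -> Tensor:
    """Per-pixel Bernoulli KL divergence (natural log); inputs pre-clamped."""
    pt, ps = as_tensor(p_teacher), as_tensor(p_student)
    if pt.shape != ps.shape:
        raise ValueError(f"shape mismatch: {pt.shape} vs {ps.shape}")
    return pt * (pt / ps).log() + (1.0 - pt) * ((1.0 - pt) / (1.0 - ps)).log()


def distillation_loss(z_teacher, z_student, cfg: DistillationConfig) -> Tensor:
    """Mean KL between softened teacher and student probabilities."""
    zt, zs = as_tensor(z_teacher), as_tensor(z_student)
    if zt.shape != zs.shape:
        raise ValueError(f"shape mismatch: teacher {zt.shape} vs student {zs.shape}")
    pt = clamp_probs(soften(zt.detach(), cfg.temperature, "teacher"), cfg.epsilon)
    student_scale = "teacher" if cfg.scale_student_logits else "student"
    ps = clamp_probs(soften(zs, cfg.temperature, student_scale), cfg.epsilon)
    return kl_binary(pt, ps).mean()


def avg_distillation_loss(losses):
    """Arithmetic mean of per-teacher distillation losses."""
    losses = list(losses)
    if not losses:
        raise ValueError("need at least one teacher loss")
    total = losses[0]
    for item in losses[1:]:
        total = total + item
    return total * (1.0 / len(losses))


def total_student_loss(avg_distillation, hard, cfg: DistillationConfig):
    """Weighted total: alpha*avg + (1-alpha)*penalty*hard.

    The penalty factor multiplies only the hard-label (ground-truth) term.
    """
    return cfg.alpha * as_tensor(avg_distillation) + (
        (1.0 - cfg.alpha) * cfg.penalty
    ) * as_tensor(hard)


def breakdown(per_teacher, hard, cfg: DistillationConfig) -> DistillationBreakdown:
    per = tuple(float(v) for v in per_teacher)
    avg = float(avg_distillation_loss(per))
    h = float(hard)
    return DistillationBreakdown(
        per_teacher=per,
        average=avg,
        hard=h,
        total=float(total_student_loss(avg, h, cfg)),
    )
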