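"""Distillation math: softening, clamping, binary KL, loss aggregation."""

import math

import numpy as np
import pytest

from vesselkd.distill import (
    DistillationConfig,
    breakdown,
    avg_distillation_loss,
    clamp_probs,
    distillation_loss,
    kl_binary,
    soften,
    total_student_loss,
)


def bernoulli_kl(pt: float, ps: float) -> float:
    """Independent closed-form oracle for the per-pixel KL term."""
    return pt * math.log(pt / ps) + (1 - pt) * math.log((1 - pt) / (1 - ps))


class TestSoften:
    def test_zero_logit_is_half(self):
        for t in (0.5, 1.0, 3.0, 100.0):
            assert float(soften(np.array(0.0), t, "teacher")) == pytest.approx(0.5)

    def test_teacher_scaling(self):
        got = float(soften(np.array(2.0), 2.0, "teacher"))
        assert got == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))
        assert got == pytest.approx(0.731059, abs=1e-6)

    def test_student_scale_ignores_temperature(self):
        z = np.array([1.7, -0.3])
        np.testing.assert_allclose(
            soften(z, 50.0, "student").data, 1 / (1 + np.exp(-z))
        )

    def test_high_temperature_limit(self):
        assert abs(float(soften(np.array(2.0), 1e6, "teacher")) - 0.5) < 1e-5

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            soften(np.array(0.0), 0.0)


class TestClamp:
    def test_bounds(self):
        eps = 1e-7
        p = np.array([0.0, 0.5, 1.0])
        out = clamp_probs(p, eps).data
        assert out[0] == pytest.approx(eps)
        assert out[1] == 0.5
        assert out[2] == pytest.approx(1.0 - eps)

    def test_interior_unchanged(self, rng):
        p = rng.uniform(0.1, 0.9, size=50)
        np.testing.assert_array_equal(clamp_probs(p, 1e-7).data, p)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            clamp_probs(np.array([0.5]), 0.7)


class TestKlBinary:
    def test_identity_is_zero(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 4))
        np.testing.assert_allclose(kl_binary(p, p).data, 0.0, atol=1e-14)

    def test_worked_example_075_05(self):
        got = float(kl_binary(np.array(0.75), np.array(0.5)))
        assert got == pytest.approx(bernoulli_kl(0.75, 0.5), abs=1e-12)
        assert got == pytest.approx(0.130812, abs=1e-6)

    def test_asymmetry(self):
        forward = float(kl_binary(np.array(0.5), np.array(0.75)))
        assert forward == pytest.approx(0.143841, abs=1e-6)
        assert forward != pytest.approx(0.130812, abs=1e-4)

    def test_non_negative_on_grid(self):
        grid = np.linspace(1e-7, 1 - 1e-7, 41)
        pt, ps = np.meshgrid(grid, grid)
        assert (kl_binary(pt, ps).data >= -1e-12).all()

    def test_matches_oracle_on_grid(self, rng):
        for _ in range(50):
            pt, ps = rng.uniform(0.01, 0.99, size=2)
            assert float(kl_binary(np.array(pt), np.array(ps))) == pytest.approx(
                bernoulli_kl(pt, ps), rel=1e-12
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kl_binary(np.zeros(3) + 0.5, np.zeros(4) + 0.5)


class TestDistillationLoss:
    def test_equal_logits_t1_zero(self, rng):
        z = rng.normal(size=(2, 1, 8, 8))
        cfg = DistillationConfig(temperature=1.0)
        assert float(distillation_loss(z, z, cfg)) == pytest.approx(0.0, abs=1e-10)

    def test_non_negative(self, rng):
        cfg = DistillationConfig()
        for _ in range(20):
            zt = rng.normal(scale=3.0, size=(1, 1, 6, 6))
            zs = rng.normal(scale=3.0, size=(1, 1, 6, 6))
            assert float(distillation_loss(zt, zs, cfg)) >= 0.0

    def test_single_pixel_reuses_kl_oracle(self):
        cfg = DistillationConfig(temperature=1.0)
        z_t = np.array([[math.log(3.0)]])  # sigmoid -> 0.75
        z_s = np.array([[0.0]])  # sigmoid -> 0.5
        assert float(distillation_loss(z_t, z_s, cfg)) == pytest.approx(
            0.130812, abs=1e-6
        )

    def test_spatial_permutation_invariance(self, rng):
        cfg = DistillationConfig()
        zt = rng.normal(size=(1, 1, 4, 4))
        zs = rng.normal(size=(1, 1, 4, 4))
        perm = rng.permutation(16)
        zt_p = zt.reshape(-1)[perm].reshape(zt.shape)
        zs_p = zs.reshape(-1)[perm].reshape(zs.shape)
        assert float(distillation_loss(zt, zs, cfg)) == pytest.approx(
            float(distillation_loss(zt_p, zs_p, cfg)), abs=1e-12
        )

    def test_infinite_temperature_equals_uniform_teacher(self, rng):
        zs = rng.normal(size=(1, 1, 8, 8))
        zt = rng.normal(scale=5.0, size=(1, 1, 8, 8))
        hot = DistillationConfig(temperature=1e6)
        uniform_teacher = np.zeros_like(zt)  # sigmoid(0/T) = 0.5 exactly
        ref = DistillationConfig(temperature=1.0)
        assert float(distillation_loss(zt, zs, hot)) == pytest.approx(
            float(distillation_loss(uniform_teacher, zs, ref)), abs=1e-4
        )

    def test_no_gradient_reaches_teacher_logits(self, rng):
        from vesselkd.nn import Tensor

        zt = Tensor(rng.normal(size=(1, 1, 4, 4)), requires_grad=True)
        zs = Tensor(rng.normal(size=(1, 1, 4, 4)), requires_grad=True)
        loss = distillation_loss(zt, zs, DistillationConfig())
        loss.backward()
        assert zt.grad is None
        assert zs.grad is not None

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            distillation_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 8, 8)),
                              DistillationConfig())


class TestAggregation:
    def test_single_teacher_identity(self):
        assert float(avg_distillation_loss([0.37])) == pytest.approx(0.37)

    def test_arithmetic_mean(self):
        assert float(avg_distillation_loss([0.1, 0.2, 0.3])) == pytest.approx(0.2)

    def test_identical_teachers_idempotent(self):
        assert float(avg_distillation_loss([0.42, 0.42, 0.42])) == pytest.approx(0.42)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            avg_distillation_loss([])


class TestTotalLoss:
    def test_equal_weighting(self):
        cfg = DistillationConfig(alpha=0.5, penalty=1.0)
        assert float(total_student_loss(0.2, 0.4, cfg)) == pytest.approx(0.3)

    def test_penalty_multiplies_hard_term_only(self):
        cfg = DistillationConfig(alpha=0.5, penalty=10.0)
        # 0.5*0.2 + 0.5*10*0.4 = 0.1 + 2.0
        assert float(total_student_loss(0.2, 0.4, cfg)) == pytest.approx(2.1)

    def test_alpha_one_is_pure_distillation(self, rng):
        cfg = DistillationConfig(alpha=1.0)
        for hard in rng.random(5):
            assert float(total_student_loss(0.2, hard, cfg)) == pytest.approx(0.2)

    def test_alpha_zero_is_pure_supervision(self):
        cfg = DistillationConfig(alpha=0.0, penalty=1.0)
        assert float(total_student_loss(123.0, 0.4, cfg)) == pytest.approx(0.4)

    def test_linear_in_each_argument(self, rng):
        cfg = DistillationConfig(alpha=0.3, penalty=5.0)
        a, h = rng.random(2)
        base = float(total_student_loss(a, h, cfg))
        assert float(total_student_loss(2 * a, h, cfg)) - base == pytest.approx(0.3 * a)
        assert float(total_student_loss(a, 2 * h, cfg)) - base == pytest.approx(
            0.7 * 5.0 * h
        )

    def test_breakdown_consistency(self):
        cfg = DistillationConfig(alpha=0.5, penalty=10.0)
        b = breakdown([0.1, 0.2, 0.3], 0.4, cfg)
        assert b.average == pytest.approx(0.2)
        assert b.total == pytest.approx(0.5 * 0.2 + 0.5 * 10.0 * 0.4)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"temperature": 0.0},
            {"alpha": 1.5},
            {"epsilon": 0.6},
            {"epsilon": 0.0},
            {"penalty": 0.5},
            {"teacher_roles": ()},
            {"teacher_roles": ("bogus",)},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            DistillationConfig(**kwargs)

    def test_defaults_follow_protocol(self):
        cfg = DistillationConfig()
        assert cfg.temperature == 3.0
        assert cfg.alpha == 0.5
        assert cfg.epsilon == 1e-7
        assert cfg.hard_loss.name == "DiceBCELoss"
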