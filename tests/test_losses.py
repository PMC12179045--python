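"""Hard-label loss zoo: worked examples, reductions, invariances."""

import math

import numpy as np
import pytest

from vesselkd.losses import (
    LossConfig,
    LOSS_NAMES,
    bce_loss,
    combined_loss,
    combo_loss,
    dice_bce_loss,
    dice_loss,
    focal_loss,
    focal_tversky_loss,
    make_loss,
    soft_dice_loss,
    tversky_loss,
)

LN2 = math.log(2.0)


def random_maps(rng, n=16):
    p = rng.random(n)
    y = (rng.random(n) > 0.5).astype(float)
    return p, y


class TestBCE:
    def test_perfect_prediction_is_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert float(bce_loss(y, y)) <= 10 * 1e-7

    def test_single_pixel_half(self):
        assert float(bce_loss(np.array([0.5]), np.array([1.0]))) == pytest.approx(LN2)

    def test_half_everywhere_any_target(self, rng):
        y = (rng.random(20) > 0.3).astype(float)
        assert float(bce_loss(np.full(20, 0.5), y)) == pytest.approx(LN2)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros(3), np.zeros(4))


class TestDice:
    def test_full_overlap(self):
        y = np.array([1.0, 0.0, 1.0, 1.0])
        assert float(dice_loss(y, y, smooth=1.0)) == pytest.approx(0.0)

    def test_hand_computed(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        # 1 - (2*1 + 1)/(2 + 2 + 1) = 1 - 3/5
        assert float(dice_loss(p, y, smooth=1.0)) == pytest.approx(0.4)

    def test_empty_empty_convention(self):
        z = np.zeros(8)
        assert float(dice_loss(z, z, smooth=1.0)) == pytest.approx(0.0)

    def test_soft_dice_squared_denominator(self):
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 0.0])
        # 1 - (2*0.5 + 1)/(0.25+0.25 + 1 + 1) = 1 - 2/2.5
        assert float(soft_dice_loss(p, y, smooth=1.0)) == pytest.approx(1 - 2 / 2.5)


class TestTversky:
    def test_symmetric_weights_reduce_to_dice(self, rng):
        # exact with smooth=0: the smoothing constants otherwise differ by
        # the factor 2 between the dice and tversky normalisations
        for _ in range(100):
            p, y = random_maps(rng)
            assert float(tversky_loss(p, y, 0.5, 0.5, smooth=0.0)) == pytest.approx(
                float(dice_loss(p, y, smooth=0.0)), abs=1e-12
            )

    def test_symmetric_weights_close_to_dice_with_default_smooth(self, rng):
        p, y = random_maps(rng, n=256)
        assert float(tversky_loss(p, y, 0.5, 0.5)) == pytest.approx(
            float(dice_loss(p, y)), abs=0.02
        )

    def test_direct_substitution(self):
        # TP=1, FP=1, FN=1: 1 - (1+1)/(1 + 0.7 + 0.3 + 1) = 1 - 2/3
        p = np.array([1.0, 1.0, 0.0])
        y = np.array([1.0, 0.0, 1.0])
        assert float(tversky_loss(p, y, 0.7, 0.3, smooth=1.0)) == pytest.approx(1 / 3)

    def test_perfect(self):
        y = np.array([1.0, 0.0])
        assert float(tversky_loss(y, y)) == pytest.approx(0.0)


class TestFocal:
    def test_gamma_zero_is_bce(self, rng):
        for _ in range(100):
            p, y = random_maps(rng)
            assert float(focal_loss(p, y, gamma=0.0)) == pytest.approx(
                float(bce_loss(p, y)), abs=1e-12
            )

    def test_closed_form_single_pixel(self):
        # y=1, p=0.5, gamma=2: 0.25 * ln 2
        got = float(focal_loss(np.array([0.5]), np.array([1.0]), gamma=2.0))
        assert got == pytest.approx(0.25 * LN2)

    def test_perfect_prediction_near_zero(self):
        y = np.array([1.0, 0.0])
        assert float(focal_loss(y, y, gamma=2.0)) < 1e-6


class TestComposites:
    def test_combo_weight_one_is_bce(self, rng):
        p, y = random_maps(rng)
        assert float(combo_loss(p, y, weight=1.0)) == pytest.approx(float(bce_loss(p, y)))

    def test_dice_bce_additivity(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        total = float(dice_bce_loss(p, y))
        assert total == pytest.approx(float(dice_loss(p, y)) + float(bce_loss(p, y)))
        assert float(dice_loss(p, y)) == pytest.approx(0.4)

    def test_combined_is_unit_weight_sum(self, rng):
        p, y = random_maps(rng)
        assert float(combined_loss(p, y)) == pytest.approx(
            float(bce_loss(p, y)) + float(dice_loss(p, y))
        )

    def test_focal_tversky_gamma_one_is_tversky(self, rng):
        for _ in range(100):
            p, y = random_maps(rng)
            assert float(focal_tversky_loss(p, y, gamma=1.0)) == pytest.approx(
                float(tversky_loss(p, y)), abs=1e-12
            )


class TestDispatch:
    def test_dice_bce_dispatch(self, rng):
        p, y = random_maps(rng)
        handle = make_loss(LossConfig("DiceBCELoss"))
        assert float(handle(p, y)) == pytest.approx(float(dice_bce_loss(p, y)))

    def test_bce_dispatch(self, rng):
        p, y = random_maps(rng)
        assert float(make_loss(LossConfig("BCE"))(p, y)) == pytest.approx(
            float(bce_loss(p, y))
        )

    def test_unknown_name_lists_options(self):
        with pytest.raises(ValueError, match="DiceBCELoss"):
            LossConfig("FooLoss")

    @pytest.mark.parametrize("name", LOSS_NAMES)
    def test_every_loss_near_zero_at_perfect_prediction(self, name):
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        handle = make_loss(LossConfig(name))
        assert float(handle(y, y)) == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("name", LOSS_NAMES)
    def test_every_loss_non_negative_and_finite(self, name, rng):
        handle = make_loss(LossConfig(name))
        for _ in range(20):
            p, y = random_maps(rng)
            val = float(handle(p, y))
            assert val >= -1e-12 and math.isfinite(val)

    @pytest.mark.parametrize("name", LOSS_NAMES)
    def test_finite_at_saturated_probabilities(self, name, rng):
        handle = make_loss(LossConfig(name))
        p = (rng.random(32) > 0.5).astype(float)  # exactly 0/1 before clamping
        y = (rng.random(32) > 0.5).astype(float)
        assert math.isfinite(float(handle(p, y)))

    @pytest.mark.parametrize("name", LOSS_NAMES)
    def test_permutation_invariance(self, name, rng):
        handle = make_loss(LossConfig(name))
        p, y = random_maps(rng, n=64)
        perm = rng.permutation(64)
        assert float(handle(p, y)) == pytest.approx(
            float(handle(p[perm], y[perm])), abs=1e-12
        )


class TestConfigValidation:
    def test_degenerate_tversky_weights(self):
        with pytest.raises(ValueError):
            LossConfig("TverskyLoss", tversky_alpha=0.0, tversky_beta=0.0)

    def test_negative_gamma(self):
        with pytest.raises(ValueError):
            LossConfig("FocalLoss", focal_gamma=-1.0)

    def test_combo_weight_bounds(self):
        with pytest.raises(ValueError):
            LossConfig("ComboLoss", combo_weight=1.5)
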