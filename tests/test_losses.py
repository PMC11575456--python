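"""Composite-loss components: hand-computed values, identities, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hairbench as hb
from hairbench.losses import WEIGHT_PRESETS


def rand_img(rng, shape=(16, 16, 3)):
    return rng.random(shape)


class TestLossHair:
    def test_zero_for_identical_images(self, rng):
        img = rand_img(rng)
        m = rng.random((16, 16)) > 0.5
        assert hb.loss_hair(img, img, m) == 0.0

    def test_zero_for_empty_hair_set(self, rng):
        assert hb.loss_hair(rand_img(rng), rand_img(rng),
                            np.zeros((16, 16), bool)) == 0.0

    def test_single_hair_pixel_hand_value(self):
        pred = np.zeros((4, 4, 3)) + 0.5
        target = pred.copy()
        target[1, 2] = 0.1  # error 0.4 on all three channels
        m = np.zeros((4, 4), bool)
        m[1, 2] = True
        assert hb.loss_hair(pred, target, m) == pytest.approx(0.16)


class TestLossNonHair:
    def test_zero_for_identical_and_all_hair(self, rng):
        img = rand_img(rng)
        assert hb.loss_non_hair(img, img, rng.random((16, 16)) > 0.5) == 0.0
        assert hb.loss_non_hair(img, rand_img(rng),
                                np.ones((16, 16), bool)) == 0.0

    def test_uniform_offset_squared(self, rng):
        target = rand_img(rng) * 0.8
        pred = target + 0.1
        m = np.zeros((16, 16), bool)
        assert hb.loss_non_hair(pred, target, m) == pytest.approx(0.01)


class TestLossNormalized:
    def test_hand_value_2x2_single_channel(self):
        pred = np.zeros((2, 2))
        target = np.zeros((2, 2))
        target[0, 1] = 0.2
        m = np.zeros((2, 2), bool)
        m[0, 1] = True
        assert hb.loss_normalized(pred, target, m) == pytest.approx(0.01)

    def test_equals_loss_hair_scaled_by_hair_fraction(self, rng):
        pred, target = rand_img(rng), rand_img(rng)
        m = rng.random((16, 16)) > 0.7
        expected = hb.loss_hair(pred, target, m) * m.sum() / m.size
        assert hb.loss_normalized(pred, target, m) == pytest.approx(expected)

    def test_never_exceeds_loss_hair(self, rng):
        for _ in range(20):
            pred, target = rand_img(rng), rand_img(rng)
            m = rng.random((16, 16)) > rng.random()
            assert hb.loss_normalized(pred, target, m) <= \
                hb.loss_hair(pred, target, m) + 1e-12


class TestLossSSIM:
    def test_zero_for_identical(self, rng):
        img = rand_img(rng)
        assert hb.loss_ssim(img, img) == pytest.approx(0.0, abs=1e-12)

    def test_zero_for_equal_constants(self):
        a = np.full((16, 16, 3), 0.5)
        assert hb.loss_ssim(a, a.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_inverted_textured_image_is_dissimilar(self, skin_image):
        assert hb.loss_ssim(1.0 - skin_image, skin_image) > 0.5


class TestLossTV:
    def test_constant_image_zero(self):
        assert hb.loss_tv(np.full((8, 8, 3), 0.3)) == 0.0

    def test_positive_homogeneity(self, rng):
        img = rand_img(rng)
        base = hb.loss_tv(img)
        assert hb.loss_tv(0.5 * img) == pytest.approx(0.5 * base)

    def test_hand_value_2x2(self):
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        # horizontal diffs {1,1}, vertical {0,0}: mean over 4 pairs = 0.5
        assert hb.loss_tv(img) == pytest.approx(0.5)


class TestTotalLoss:
    def test_plain_sum_with_uniform_weights(self):
        w = hb.LossWeights(*WEIGHT_PRESETS["uniform"])
        comps = hb.LossComponents(0.1, 0.2, 0.3, 0.1, 0.05)
        assert hb.total_loss(comps, w) == pytest.approx(0.75)

    def test_zero_components_zero_total(self):
        comps = hb.LossComponents(0, 0, 0, 0, 0)
        assert hb.total_loss(comps, hb.LossWeights()) == 0.0

    def test_tuned_weights_unit_components(self):
        comps = hb.LossComponents(1, 1, 1, 1, 1)
        assert hb.total_loss(comps, hb.LossWeights.preset("tuned")) == \
            pytest.approx(7.8)

    def test_linear_in_each_component_and_weight(self, rng):
        vals = rng.random(5)
        w = hb.LossWeights(*rng.random(5))
        base = hb.total_loss(tuple(vals), w)
        for i in range(5):
            bumped = vals.copy()
            bumped[i] += 1.0
            lam = [w.hair, w.non_hair, w.normalized, w.ssim, w.tv][i]
            assert hb.total_loss(tuple(bumped), w) == pytest.approx(base + lam)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=5, max_size=5),
           st.lists(st.floats(0.0, 5.0, allow_nan=False), min_size=5, max_size=5),
           st.floats(0.0, 3.0, allow_nan=False))
    def test_scaling_all_components_scales_total(self, comps, lams, c):
        w = hb.LossWeights(*lams)
        base = hb.total_loss(tuple(comps), w)
        scaled = hb.total_loss(tuple(c * x for x in comps), w)
        assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            hb.LossWeights(-1, 1, 1, 1, 1)

    def test_presets_match_reported_configurations(self):
        assert WEIGHT_PRESETS["tuned"] == (2.5, 3.5, 0.3, 1.0, 0.5)
        assert hb.LossWeights.parse("2.5,3.5,0.3,1,0.5") == \
            hb.LossWeights.preset("tuned")

    def test_weights_load_from_yaml(self, tmp_path):
        p = tmp_path / "w.yaml"
        p.write_text("hair: 2.5\nnon_hair: 3.5\nnormalized: 0.3\nssim: 1\ntv: 0.5\n")
        assert hb.LossWeights.parse(str(p)) == hb.LossWeights.preset("tuned")
        q = tmp_path / "v.yml"
        q.write_text("[1, 1, 1, 1, 1]\n")
        assert hb.LossWeights.parse(str(q)) == hb.LossWeights.preset("uniform")


class TestJointInvariants:
    def test_identical_prediction_leaves_only_tv(self, paired_sample):
        clean = paired_sample.clean
        m = hb.binarize_mask(paired_sample.mask)
        w = hb.LossWeights()
        total, comps = hb.composite_loss(clean, clean, m, w)
        assert comps.hair == comps.non_hair == comps.normalized == 0.0
        assert comps.ssim == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(w.tv * hb.loss_tv(clean))

    def test_all_components_nonnegative(self, rng):
        for _ in range(10):
            pred, target = rand_img(rng), rand_img(rng)
            m = rng.random((16, 16)) > 0.5
            _, comps = hb.composite_loss(pred, target, m, hb.LossWeights())
            assert min(comps.hair, comps.non_hair, comps.normalized,
                       comps.ssim, comps.tv) >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            hb.loss_hair(rand_img(rng), rand_img(rng, (8, 8, 3)),
                         np.zeros((16, 16), bool))
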