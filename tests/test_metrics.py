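"""Quality metrics against independent oracles, plus near-mask PRF."""

import numpy as np
import pytest
from scipy.signal import convolve2d
from skimage.metrics import structural_similarity as sk_ssim

import hairbench as hb
from hairbench.metrics import MSSSIM_WEIGHTS, gaussian_window


def rand_pair(rng, shape=(32, 32, 3), noise=0.1):
    a = rng.random(shape)
    b = np.clip(a + rng.normal(0, noise, shape), 0, 1)
    return a, b


# ----------------------------------------------------------------- oracles

def mse_brute(a, b):
    """Explicit double-loop mean squared error."""
    total, n = 0.0, 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for c in range(a.shape[2]):
                total += (a[i, j, c] - b[i, j, c]) ** 2
                n += 1
    return total / n


def msssim_reference(a, b, scales):
    """Independent MS-SSIM oracle built on scipy.signal.convolve2d."""
    k = gaussian_window(11, 1.5)
    c1, c2 = 0.01 ** 2, 0.03 ** 2

    def stats(x, y):
        ssims, css = [], []
        for ch in range(x.shape[2]):
            xc, yc = x[:, :, ch], y[:, :, ch]
            f = lambda img: convolve2d(img, k, mode="valid")
            mx, my = f(xc), f(yc)
            vx = f(xc * xc) - mx * mx
            vy = f(yc * yc) - my * my
            cxy = f(xc * yc) - mx * my
            lum_map = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
            cs_map = (2 * cxy + c2) / (vx + vy + c2)
            ssims.append((lum_map * cs_map).mean())
            css.append(cs_map.mean())
        return np.mean(ssims), np.mean(css)

    w = np.asarray(MSSSIM_WEIGHTS[:scales])
    w = w / w.sum()
    out = 1.0
    for lvl in range(scales):
        full, cs = stats(a, b)
        if lvl == scales - 1:
            out *= max(full, 1e-8) ** w[lvl]
        else:
            out *= max(cs, 1e-8) ** w[lvl]
            h, ww = a.shape[:2]
            a = a[:h - h % 2, :ww - ww % 2]
            b = b[:h - h % 2, :ww - ww % 2]
            a = a.reshape(a.shape[0] // 2, 2, a.shape[1] // 2, 2, -1).mean(axis=(1, 3))
            b = b.reshape(b.shape[0] // 2, 2, b.shape[1] // 2, 2, -1).mean(axis=(1, 3))
    return out


# ------------------------------------------------------------------- tests

class TestErrors:
    def test_identical_images(self, rng):
        a = rng.random((8, 8, 3))
        assert hb.mse(a, a) == 0.0 and hb.mae(a, a) == 0.0

    def test_constant_offset_closed_form(self, rng):
        a = rng.random((8, 8, 3)) * 0.8
        assert hb.mse(a + 0.1, a) == pytest.approx(0.01)
        assert hb.mae(a + 0.1, a) == pytest.approx(0.1)

    def test_matches_double_loop_oracle(self, rng):
        a, b = rand_pair(rng, (8, 8, 3), 0.3)
        assert abs(hb.mse(a, b) - mse_brute(a, b)) < 1e-12

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            hb.mse(rng.random((8, 8)), rng.random((9, 8)))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.random((32, 32, 3))
        assert hb.ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rand_pair(rng)
        assert hb.ssim(a, b) == pytest.approx(hb.ssim(b, a), abs=1e-12)

    def test_matches_skimage_reference(self, rng):
        for _ in range(20):
            a, b = rand_pair(rng, noise=rng.uniform(0.02, 0.4))
            ref = sk_ssim(a, b, channel_axis=2, gaussian_weights=True,
                          sigma=1.5, use_sample_covariance=False,
                          data_range=1.0)
            assert hb.ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_image_smaller_than_window_rejected(self, rng):
        with pytest.raises(ValueError):
            hb.ssim(rng.random((8, 8)), rng.random((8, 8)))


class TestMSSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.random((64, 64, 3))
        assert hb.ms_ssim(a, a) == pytest.approx(1.0, abs=1e-10)

    def test_single_scale_reduces_to_ssim(self, rng):
        a, b = rand_pair(rng, (48, 48, 3))
        assert hb.ms_ssim(a, b, scales=1) == pytest.approx(hb.ssim(a, b), abs=1e-12)

    def test_matches_independent_reference(self, rng):
        for _ in range(10):
            a, b = rand_pair(rng, (64, 64, 3), rng.uniform(0.05, 0.3))
            ref = msssim_reference(a.copy(), b.copy(), scales=3)
            assert hb.ms_ssim(a, b, scales=3) == pytest.approx(ref, abs=1e-5)

    def test_monotone_degradation_with_noise(self, skin_image):
        rng = np.random.default_rng(0)
        levels = np.linspace(0.01, 0.4, 20)
        vals = []
        for s in levels:
            reps = [hb.ms_ssim(skin_image, np.clip(
                skin_image + rng.normal(0, s, skin_image.shape), 0, 1), scales=3)
                for _ in range(3)]
            vals.append(np.mean(reps))
        # strictly decreasing on average across the noise ramp
        assert all(x > y for x, y in zip(vals[:-1], vals[1:]))

    def test_too_many_scales_rejected(self, rng):
        with pytest.raises(ValueError):
            hb.ms_ssim(rng.random((64, 64)), rng.random((64, 64)), scales=5)


class TestPRF:
    def _mask(self):
        m = np.zeros((40, 40))
        m[18:22, 5:35] = 1.0
        return m

    def test_no_change_means_zero_recall(self):
        m = self._mask()
        hairy = np.random.default_rng(0).random((40, 40, 3))
        rec = hb.prf_near_mask(hairy, hairy, None, m)
        assert rec.recall == 0.0 and rec.no_predictions

    def test_perfect_detector(self):
        m = self._mask()
        rng = np.random.default_rng(1)
        hairy = rng.random((40, 40, 3))
        removed = hairy.copy()
        removed[m > 0.5] += 0.2
        rec = hb.prf_near_mask(removed, hairy, None, m)
        assert rec.precision == rec.recall == rec.f1 == 1.0

    def test_f1_satisfies_harmonic_mean_invariant(self, paired_sample):
        rng = np.random.default_rng(5)
        removed = np.clip(paired_sample.hairy +
                          rng.normal(0, 0.04, paired_sample.hairy.shape), 0, 1)
        rec = hb.prf_near_mask(removed, paired_sample.hairy, None,
                               paired_sample.mask)
        assert 0.0 < rec.precision <= 1.0 and 0.0 < rec.recall <= 1.0
        expected = 2 * rec.precision * rec.recall / (rec.precision + rec.recall)
        assert rec.f1 == pytest.approx(expected, abs=1e-12)

    def test_precision_nondecreasing_in_dilation_radius(self, paired_sample):
        rng = np.random.default_rng(2)
        removed = np.clip(paired_sample.hairy +
                          rng.normal(0, 0.05, paired_sample.hairy.shape), 0, 1)
        precisions = [hb.prf_near_mask(removed, paired_sample.hairy, None,
                                       paired_sample.mask, dilation_radius=r).precision
                      for r in (0, 2, 5, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(precisions[:-1], precisions[1:]))

    def test_empty_truth_flagged(self):
        img = np.random.default_rng(3).random((20, 20, 3))
        rec = hb.prf_near_mask(img, img, None, np.zeros((20, 20)))
        assert rec.empty_truth and rec.recall == 0.0
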