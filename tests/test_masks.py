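"""Hair-mask generation: Bezier geometry, sampling, rasterization, blur."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hairbench as hb
from hairbench.masks import bezier_polyline

coords = st.floats(-100.0, 100.0, allow_nan=False)


def de_casteljau(cps, t):
    """Independent Bezier oracle: repeated linear interpolation."""
    pts = [np.asarray(p, dtype=float) for p in cps]
    while len(pts) > 1:
        pts = [(1 - t) * a + t * b for a, b in zip(pts[:-1], pts[1:])]
    return pts[0]


class TestBezierPoint:
    def test_endpoints(self):
        cps = [(0.0, 0.0), (2.0, 5.0), (-1.0, 3.0), (4.0, 4.0)]
        assert np.allclose(hb.bezier_point(cps, 0.0), cps[0])
        assert np.allclose(hb.bezier_point(cps, 1.0), cps[3])

    def test_midpoint_hand_value(self):
        cps = [(0, 0), (0, 1), (1, 1), (1, 0)]
        assert np.allclose(hb.bezier_point(cps, 0.5), (0.5, 0.75))

    def test_matches_de_casteljau_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            cps = rng.uniform(-50, 50, size=(4, 2))
            t = rng.uniform()
            assert np.abs(hb.bezier_point(cps, t) - de_casteljau(cps, t)).max() < 1e-9

    def test_collinear_control_points_stay_on_segment(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p0, p3 = rng.uniform(-10, 10, (2, 2))
            lam = np.sort(rng.uniform(0, 1, 2))
            cps = [p0, p0 + lam[0] * (p3 - p0), p0 + lam[1] * (p3 - p0), p3]
            pts = bezier_polyline(cps, 25)
            d = p3 - p0
            # distance from each curve point to the segment p0-p3
            t = ((pts - p0) @ d) / (d @ d)
            proj = p0 + np.clip(t, 0, 1)[:, None] * d
            assert np.linalg.norm(pts - proj, axis=1).max() < 1e-6

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(coords, coords), min_size=4, max_size=4),
           st.floats(0.0, 1.0, allow_nan=False))
    def test_curve_point_stays_in_control_point_bounding_box(self, cps, t):
        # Bernstein weights are a convex combination, so the curve never
        # leaves the convex hull (hence the bounding box) of its controls
        pt = hb.bezier_point(cps, t)
        arr = np.asarray(cps)
        assert np.all(pt >= arr.min(axis=0) - 1e-9)
        assert np.all(pt <= arr.max(axis=0) + 1e-9)

    def test_domain_errors(self):
        cps = [(0, 0), (0, 1), (1, 1), (1, 0)]
        with pytest.raises(ValueError):
            hb.bezier_point(cps, 1.5)
        with pytest.raises(ValueError):
            hb.bezier_point([(0, 0), (1, 1)], 0.5)


class TestStrandSampling:
    def test_deterministic_given_seed(self):
        cfg = hb.MaskGenConfig()
        a = hb.sample_strand_spec(cfg, np.random.default_rng(5))
        b = hb.sample_strand_spec(cfg, np.random.default_rng(5))
        assert np.array_equal(a.control_points, b.control_points)
        assert a.thickness == b.thickness and a.arc_length == b.arc_length

    def test_arc_length_always_in_range(self):
        cfg = hb.MaskGenConfig()
        rng = np.random.default_rng(2)
        for _ in range(200):
            spec = hb.sample_strand_spec(cfg, rng)
            assert 100.0 <= spec.arc_length <= 900.0
            # the spec's recorded length matches the resampled polyline
            measured = np.sqrt(np.diff(bezier_polyline(
                spec.control_points, cfg.curve_samples), axis=0) ** 2
                @ np.ones(2)).sum()
            assert measured == pytest.approx(spec.arc_length, rel=1e-9)

    def test_thickness_uniform_over_levels(self):
        cfg = hb.MaskGenConfig()
        rng = np.random.default_rng(3)
        draws = np.array([hb.sample_strand_spec(cfg, rng).thickness
                          for _ in range(10_000)])
        freq = np.bincount(draws, minlength=5)[1:5] / draws.size
        se = np.sqrt(0.25 * 0.75 / draws.size)
        assert np.abs(freq - 0.25).max() < 3 * se


class TestRasterization:
    def test_degenerate_strand_is_a_disc(self):
        spec = hb.StrandSpec(np.full((4, 2), 20.0), thickness=4, arc_length=0.0)
        canvas = np.zeros((41, 41))
        hb.rasterize_strand(canvas, spec)
        dist = np.hypot(*np.mgrid[0:41, 0:41] - 20.0)
        assert np.all(canvas[dist <= 1.5] == 1.0)   # r=2, full inside r-0.5
        assert np.all(canvas[dist >= 2.5] == 0.0)   # zero beyond r+0.5
        assert canvas.max() == 1.0

    def test_strand_outside_canvas_leaves_it_unchanged(self):
        spec = hb.StrandSpec(np.array([[100, 100], [110, 120], [130, 110],
                                       [140, 140]], float), 3, 80.0)
        canvas = np.zeros((32, 32))
        hb.rasterize_strand(canvas, spec)
        assert canvas.sum() == 0.0

    def test_horizontal_stroke_coverage(self):
        # straight strand along row 10, thickness 1
        cps = np.array([[10.0, 2.0], [10.0, 10.0], [10.0, 20.0], [10.0, 28.0]])
        spec = hb.StrandSpec(cps, thickness=1, arc_length=26.0)
        canvas = np.zeros((21, 31))
        hb.rasterize_strand(canvas, spec)
        assert np.all(canvas[10, 2:29] >= 0.5)
        assert np.all(canvas[:8] == 0.0) and np.all(canvas[13:] == 0.0)

    def test_coverage_matches_supersampling_for_axis_aligned_stroke(self):
        # for an axis-aligned stroke the signed-distance falloff equals the
        # exact fractional pixel coverage; check against 64x supersampling
        cps = np.array([[10.3, 2.0], [10.3, 10.0], [10.3, 20.0], [10.3, 28.0]])
        spec = hb.StrandSpec(cps, thickness=2, arc_length=26.0)
        canvas = np.zeros((21, 31))
        hb.rasterize_strand(canvas, spec)
        sub = np.linspace(-0.5, 0.5, 64, endpoint=False) + 1 / 128
        for row in range(8, 14):
            exact = np.mean(np.abs(row + sub - 10.3) <= 1.0)
            assert canvas[row, 15] == pytest.approx(exact, abs=1 / 64)


class TestGenerateMask:
    def test_forced_count_and_spec_bookkeeping(self, small_mask_config):
        from dataclasses import replace
        cfg = replace(small_mask_config, num_hairs_range=(3, 3))
        mask = hb.generate_mask(cfg, np.random.default_rng(0))
        assert mask.strand_count == 3 == len(mask.strand_specs)

    def test_same_seed_bit_identical(self, small_mask_config):
        a = hb.generate_mask(small_mask_config, np.random.default_rng(9))
        b = hb.generate_mask(small_mask_config, np.random.default_rng(9))
        assert np.array_equal(a.values, b.values)

    def test_values_in_unit_interval(self, small_mask_config):
        rng = np.random.default_rng(4)
        for _ in range(5):
            m = hb.generate_mask(small_mask_config, rng)
            assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_combined_mask_is_pointwise_max_of_layers(self, small_mask_config):
        m = hb.generate_mask(small_mask_config, np.random.default_rng(6))
        assert np.array_equal(m.values, np.max(m.layers, axis=0))

    def test_invalid_hair_range_rejected(self):
        with pytest.raises(ValueError):
            hb.MaskGenConfig(num_hairs_range=(0, 5))


class TestBinarize:
    def test_definition_on_known_values(self):
        m = np.array([[0.0, 0.4], [0.6, 1.0]])
        assert hb.binarize_mask(m, 0.5).tolist() == [[False, False], [True, True]]
        assert not hb.binarize_mask(np.zeros((4, 4)), 0.5).any()
        assert hb.binarize_mask(np.ones((4, 4)), 0.5).all()

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            hb.binarize_mask(np.zeros((2, 2)), 0.0)


def test_mask_png_roundtrip(tmp_path, small_mask_config):
    m = hb.generate_mask(small_mask_config, np.random.default_rng(8))
    hb.save_mask(m, tmp_path / "m.png")
    loaded = hb.load_mask(tmp_path / "m.png")
    assert np.abs(loaded.values - m.values).max() <= 0.5 / 255
    assert loaded.strand_count == m.strand_count
    assert loaded.strand_specs[0].thickness == m.strand_specs[0].thickness
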