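"""Canny stage-by-stage checks against straight-line loop oracles."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from folliseg import edge_ops
from reference_canny import (ref_canny, ref_hysteresis, ref_magnitude_angle,
                             ref_nms, ref_sobel)


def grad_field(dx, dy):
    mag, ang = edge_ops.magnitude_angle(dx, dy)
    return edge_ops.GradientField(dx=dx, dy=dy, magnitude=mag, angle=ang)


class TestSobelGradients:
    def test_constant_image_has_zero_gradient(self):
        g = edge_ops.sobel_gradients(np.full((9, 9), 0.5))
        assert np.all(g.dx == 0) and np.all(g.dy == 0)
        assert np.all(g.magnitude == 0) and np.all(g.angle == 0)

    def test_vertical_step_symmetry(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        g = edge_ops.sobel_gradients(img)
        inner = g.dy[1:-1, 1:-1]
        assert np.all(inner == 0)          # no vertical variation
        assert np.all(g.dx[1:-1, 4] > 0)   # horizontal derivative at the step

    def test_matches_loop_oracle(self, rng):
        img = rng.uniform(0, 1, (7, 7))
        g = edge_ops.sobel_gradients(img)
        dx_ref, dy_ref = ref_sobel(img.tolist())
        np.testing.assert_allclose(g.dx, np.array(dx_ref), atol=1e-12)
        np.testing.assert_allclose(g.dy, np.array(dy_ref), atol=1e-12)

    @pytest.mark.parametrize("shape", [(2, 5), (5, 2), (1, 1)])
    def test_too_small_image_rejected(self, shape):
        with pytest.raises(ValueError, match="at least 3x3"):
            edge_ops.sobel_gradients(np.zeros(shape))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            edge_ops.sobel_gradients(np.full((5, 5), 1.5))


class TestMagnitudeAngle:
    def test_three_four_five(self):
        mag, ang = edge_ops.magnitude_angle(np.array([[3.0]]), np.array([[4.0]]))
        assert mag[0, 0] == pytest.approx(5.0)
        assert ang[0, 0] == pytest.approx(np.arctan2(4.0, 3.0))

    def test_zero_gradient_convention(self):
        mag, ang = edge_ops.magnitude_angle(np.zeros((3, 3)), np.zeros((3, 3)))
        assert np.all(mag == 0) and np.all(ang == 0)

    def test_matches_scalar_oracle(self, rng):
        dx = rng.normal(size=(6, 6))
        dy = rng.normal(size=(6, 6))
        mag, ang = edge_ops.magnitude_angle(dx, dy)
        mag_ref, ang_ref = ref_magnitude_angle(dx.tolist(), dy.tolist())
        np.testing.assert_allclose(mag, np.array(mag_ref), rtol=1e-15)
        np.testing.assert_allclose(ang, np.array(ang_ref), rtol=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            edge_ops.magnitude_angle(np.zeros((3, 3)), np.zeros((3, 4)))


class TestNonMaxSuppression:
    def test_zero_field_stays_zero(self):
        g = grad_field(np.zeros((5, 5)), np.zeros((5, 5)))
        assert np.all(edge_ops.non_max_suppression(g) == 0)

    def test_single_pixel_ridge_survives(self):
        # a one-pixel-wide vertical ridge with purely horizontal gradient
        dx = np.zeros((7, 7))
        dx[:, 3] = 1.0
        g = grad_field(dx, np.zeros_like(dx))
        thin = edge_ops.non_max_suppression(g)
        np.testing.assert_array_equal(thin, g.magnitude)

    def test_ramp_profile_thins_to_single_column(self):
        # 3-pixel-wide ramp across a vertical edge: only the crest survives
        dx = np.zeros((7, 9))
        dx[:, 3], dx[:, 4], dx[:, 5] = 0.5, 1.0, 0.5
        g = grad_field(dx, np.zeros_like(dx))
        thin = edge_ops.non_max_suppression(g)
        support = thin > 0
        assert np.all(support.sum(axis=1) <= 1)
        assert np.all(support[:, 4])

    def test_plateau_thins_toward_lower_index(self):
        dx = np.zeros((5, 8))
        dx[:, 3] = dx[:, 4] = 1.0
        g = grad_field(dx, np.zeros_like(dx))
        thin = edge_ops.non_max_suppression(g)
        assert np.all(thin[:, 3] == 1.0) and np.all(thin[:, 4] == 0.0)

    def test_matches_neighbor_comparison_oracle(self, rng):
        for _ in range(10):
            dx = rng.normal(size=(9, 9))
            dy = rng.normal(size=(9, 9))
            g = grad_field(dx, dy)
            thin = edge_ops.non_max_suppression(g)
            ref = np.array(ref_nms(g.magnitude.tolist(), g.angle.tolist()))
            np.testing.assert_array_equal(thin, ref)

    def test_output_bounded_by_magnitude(self, rng):
        g = grad_field(rng.normal(size=(12, 12)), rng.normal(size=(12, 12)))
        thin = edge_ops.non_max_suppression(g)
        assert np.all(thin <= g.magnitude)


class TestHysteresis:
    def test_all_weak_gives_empty_map(self):
        thin = np.full((6, 6), 0.05)
        assert edge_ops.hysteresis_threshold(thin, 0.1, 0.2).sum() == 0

    def test_all_strong_keeps_support(self, rng):
        thin = np.where(rng.uniform(size=(8, 8)) > 0.5, 0.9, 0.0)
        em = edge_ops.hysteresis_threshold(thin, 0.1, 0.2)
        np.testing.assert_array_equal(em, (thin > 0).astype(np.uint8))

    def test_weak_chain_linked_to_strong_survives(self):
        thin = np.zeros((5, 10))
        thin[2, 1:8] = 0.15          # weak chain
        thin[2, 8] = 0.9             # strong anchor at one end
        em = edge_ops.hysteresis_threshold(thin, 0.1, 0.2)
        assert np.all(em[2, 1:9] == 1)
        thin[2, 8] = 0.15            # anchor removed: isolated weak chain
        assert edge_ops.hysteresis_threshold(thin, 0.1, 0.2).sum() == 0

    def test_matches_bfs_flood_fill_oracle(self, rng):
        for _ in range(10):
            thin = np.where(rng.uniform(size=(12, 12)) > 0.6,
                            rng.uniform(size=(12, 12)), 0.0)
            em = edge_ops.hysteresis_threshold(thin, 0.2, 0.5)
            ref = np.array(ref_hysteresis(thin.tolist(), 0.2, 0.5), dtype=np.uint8)
            np.testing.assert_array_equal(em, ref)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="low <= high"):
            edge_ops.hysteresis_threshold(np.zeros((4, 4)), 0.5, 0.2)


class TestCanny:
    def test_rectangle_gives_closed_one_pixel_loop(self):
        img = np.zeros((12, 12))
        img[3:9, 2:10] = 1.0
        em = edge_ops.canny(img)
        # one 8-connected edge curve that separates inside from outside
        _, n_edge = ndimage.label(em, structure=np.ones((3, 3)))
        assert n_edge == 1
        _, n_bg = ndimage.label(em == 0)  # 4-connectivity
        assert n_bg == 2
        # every edge pixel within 1 px (chebyshev) of the true boundary ring
        boundary = img.astype(bool) ^ ndimage.binary_erosion(img.astype(bool))
        near = ndimage.binary_dilation(boundary, structure=np.ones((3, 3)))
        assert np.all(near[em.astype(bool)])

    def test_constant_image_has_no_edges(self):
        assert edge_ops.canny(np.full((16, 16), 0.3)).sum() == 0

    def test_deterministic(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        np.testing.assert_array_equal(edge_ops.canny(img), edge_ops.canny(img))

    def test_raising_high_threshold_never_adds_edges(self, rng):
        img = rng.uniform(0, 1, (24, 24))
        low = 0.3
        highs = [0.4, 0.8, 1.2, 1.6]
        maps = [edge_ops.canny(img, low, h) for h in highs]
        for smaller, larger in itertools.pairwise(maps):
            assert np.all(larger <= smaller)

    def test_edge_support_subset_of_thin_support(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        g = edge_ops.sobel_gradients(img)
        thin = edge_ops.non_max_suppression(g)
        em = edge_ops.canny(img)
        assert np.all(thin[em.astype(bool)] > 0)

    def test_smoothing_reduces_edge_count_on_noise(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        plain = edge_ops.canny(img).sum()
        smoothed = edge_ops.canny(img, smooth_sigma=2.0).sum()
        assert smoothed < plain

    def test_matches_reference_on_random_images(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 1, (16, 16))
            low = 0.1 * edge_ops.MAX_GRADIENT_MAGNITUDE
            high = 0.2 * edge_ops.MAX_GRADIENT_MAGNITUDE
            ref = np.array(ref_canny(img.tolist(), low, high), dtype=np.uint8)
            np.testing.assert_array_equal(edge_ops.canny(img, low, high), ref)


class TestSoftEdge:
    def test_constant_map_gives_zero(self):
        # exactly zero for dyadic constants; round-off only otherwise
        assert np.all(edge_ops.soft_edge(np.full((8, 8), 0.5)) == 0)
        np.testing.assert_allclose(edge_ops.soft_edge(np.full((8, 8), 0.7)),
                                   0.0, atol=1e-12)

    def test_rectangle_support_hugs_canny_edge(self):
        img = np.zeros((12, 12))
        img[3:9, 2:10] = 1.0
        soft = edge_ops.soft_edge(img)
        em = edge_ops.canny(img)
        near = ndimage.binary_dilation(em.astype(bool), structure=np.ones((3, 3)))
        assert np.all(near[soft > 0])

    def test_positively_homogeneous(self, rng):
        p = rng.uniform(0, 1, (10, 10))
        np.testing.assert_allclose(edge_ops.soft_edge(0.5 * p),
                                   0.5 * edge_ops.soft_edge(p), atol=1e-12)

    def test_range_bounded_for_any_probability_map(self, rng):
        for _ in range(20):
            p = (rng.uniform(0, 1, (8, 8)) > rng.uniform()).astype(float)
            s = edge_ops.soft_edge(p)
            assert s.min() >= 0.0 and s.max() <= 1.0

    def test_normaliser_is_attainable_maximum(self):
        # max Sobel magnitude over [0,1] images = max over binary 3x3 patches
        # (maximum of a convex quadratic over the unit box sits at a vertex)
        best = 0.0
        for bits in itertools.product([0.0, 1.0], repeat=9):
            patch = np.array(bits).reshape(3, 3)
            dx = float(np.sum(patch * edge_ops.SOBEL_KX))
            dy = float(np.sum(patch * edge_ops.SOBEL_KY))
            best = max(best, np.hypot(dx, dy))
        assert best == pytest.approx(edge_ops.MAX_GRADIENT_MAGNITUDE, abs=1e-12)
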