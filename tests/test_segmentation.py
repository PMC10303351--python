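"""Gabor bank, iterative threshold and mask post-processing, with oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundushsi import (
    GaborParams,
    dice_coefficient,
    estimate_fov_mask,
    extract_green,
    gabor_kernel,
    iterative_threshold,
    magnitude_response,
    make_phantom_fundus,
    max_response_map,
    oriented_response,
    remove_small_objects,
    segment_vessels,
)
from fundushsi.segmentation import OrientedResponse

from ._oracles import fixed_point_scan, naive_correlation

SMALL = GaborParams(theta_step=np.pi / 8, kernel_halfwidth=6)


class TestGaborKernel:
    def test_real_kernel_value_at_origin(self):
        p = GaborParams()
        kr, ki = gabor_kernel(p, 0.3)
        h = p.kernel_halfwidth
        assert kr[h, h] == pytest.approx(1.0 / (2 * np.pi * p.sigma_x * p.sigma_y))
        assert ki[h, h] == 0.0

    @pytest.mark.parametrize("theta", np.linspace(-np.pi / 2, np.pi / 2, 181)[::20])
    def test_parity_even_real_odd_imaginary(self, theta):
        kr, ki = gabor_kernel(GaborParams(), theta)
        np.testing.assert_allclose(kr, kr[::-1, ::-1], atol=1e-14)
        np.testing.assert_allclose(ki, -ki[::-1, ::-1], atol=1e-14)

    def test_quarter_turn_relates_kernels_by_grid_rotation(self):
        p = GaborParams()
        kr0, ki0 = gabor_kernel(p, 0.0)
        kr90, ki90 = gabor_kernel(p, np.pi / 2)
        # rotating the grid by 90 degrees maps theta=0 onto theta=pi/2
        np.testing.assert_allclose(kr90, np.rot90(kr0), atol=1e-12)
        np.testing.assert_allclose(np.abs(ki90), np.abs(np.rot90(ki0)), atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GaborParams(f0=0.0)
        with pytest.raises(ValueError):
            GaborParams(sigma_x=-1.0)
        with pytest.raises(ValueError):
            gabor_kernel(GaborParams(), 2.0)

    def test_default_grid_has_181_angles(self):
        assert GaborParams().theta_grid.size == 181


class TestOrientedResponse:
    def test_constant_image_gives_dc_gain_and_zero_imaginary(self):
        c = 0.37
        img = np.full((20, 20), c)
        kr, ki = gabor_kernel(SMALL, 0.5)
        resp = oriented_response(img, SMALL, 0.5)
        np.testing.assert_allclose(resp.G_real, c * kr.sum(), atol=1e-10)
        np.testing.assert_allclose(resp.G_imag, 0.0, atol=1e-10)
        assert abs(ki.sum()) < 1e-14  # odd kernel sums to zero

    def test_impulse_reproduces_flipped_kernel(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        kr, _ = gabor_kernel(SMALL, 0.9)
        resp = oriented_response(img, SMALL, 0.9)
        h = SMALL.kernel_halfwidth
        # correlation with an impulse centers the point-reflected kernel
        np.testing.assert_allclose(
            resp.G_real[15 - h : 15 + h + 1, 15 - h : 15 + h + 1],
            kr[::-1, ::-1],
            atol=1e-10,
        )

    @pytest.mark.parametrize("theta", [-1.2, 0.0, 0.7])
    def test_matches_naive_loop_correlation(self, rng, theta):
        img = rng.random((32, 32))
        kr, ki = gabor_kernel(SMALL, theta)
        resp = oriented_response(img, SMALL, theta)
        np.testing.assert_allclose(resp.G_real, naive_correlation(img, kr), atol=1e-8)
        np.testing.assert_allclose(resp.G_imag, naive_correlation(img, ki), atol=1e-8)


class TestMagnitudeAndMax:
    def test_three_four_five(self):
        resp = OrientedResponse(np.full((2, 2), 3.0), np.full((2, 2), 4.0), 0.0)
        np.testing.assert_allclose(magnitude_response(resp), 5.0)

    def test_zero_imaginary_gives_absolute_real(self, rng):
        g = rng.normal(size=(5, 5))
        resp = OrientedResponse(g, np.zeros_like(g), 0.0)
        np.testing.assert_allclose(magnitude_response(resp), np.abs(g))

    def test_matches_elementwise_recomputation(self, rng):
        gr, gi = rng.normal(size=(2, 8, 8))
        resp = OrientedResponse(gr, gi, 0.0)
        np.testing.assert_allclose(
            magnitude_response(resp), np.sqrt(gr**2 + gi**2), atol=1e-12
        )

    def test_single_angle_bank_equals_that_magnitude(self, rng):
        img = rng.random((24, 24))
        p = GaborParams(theta_step=10.0)  # grid collapses to one angle
        assert p.theta_grid.size == 1
        theta = p.theta_grid[0]
        r = max_response_map(img, p).R
        np.testing.assert_allclose(
            r, magnitude_response(oriented_response(img, p, theta)), atol=1e-10
        )

    def test_max_dominates_every_angle_and_subsets(self, rng):
        img = rng.random((24, 24))
        p = GaborParams(theta_step=np.pi / 18, kernel_halfwidth=5)
        r = max_response_map(img, p).R
        for theta in p.theta_grid:
            mag = magnitude_response(oriented_response(img, p, theta))
            assert np.all(r >= mag - 1e-10)

    def test_argmax_orientation_tracks_a_drawn_line(self):
        # vertical line: intensity varies along x, so the wave vector
        # (kernel x' axis) aligns at theta = 0
        img = np.zeros((48, 48))
        img[:, 23:26] = 1.0
        p = GaborParams(kernel_halfwidth=8)
        rm = max_response_map(img, p)
        center = rm.argmax_theta[10:38, 24]
        # mode of centerline angles within 3 degrees of 0 (mod pi)
        ang = np.median(np.abs(((center + np.pi / 2) % np.pi) - np.pi / 2))
        assert np.rad2deg(ang) <= 3.0


class TestIterativeThreshold:
    def test_two_level_image_splits_midway(self):
        res = iterative_threshold(np.array([0, 0, 0, 255, 255, 255]), epsilon=0.5)
        assert res.threshold == pytest.approx(127.5)
        assert res.iterations <= 2
        assert not res.degenerate

    def test_flat_input_degenerate(self):
        res = iterative_threshold(np.array([10.0, 10, 10, 10]))
        assert res.threshold == 10.0
        assert res.iterations == 0
        assert res.degenerate

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            iterative_threshold(np.array([]))

    def test_matches_fixed_point_scan_on_random_8bit_images(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            vals = rng.integers(0, 256, size=(32, 32))
            res = iterative_threshold(vals, epsilon=0.5)
            points = fixed_point_scan(vals)
            assert points, "oracle found no fixed point"
            assert min(abs(res.threshold - fp) for fp in points) <= 0.5

    @given(
        st.lists(st.integers(min_value=0, max_value=255), min_size=2, max_size=200)
    )
    @settings(max_examples=50, deadline=None)
    def test_returned_threshold_is_an_epsilon_fixed_point(self, values):
        vals = np.asarray(values, dtype=float)
        res = iterative_threshold(vals, epsilon=0.5)
        if res.degenerate:
            return
        t = res.threshold
        low = vals[vals <= t]
        high = vals[vals > t]
        if low.size and high.size:
            assert abs(t - 0.5 * (low.mean() + high.mean())) < 0.5


class TestRemoveSmallObjects:
    def test_small_blob_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2:5] = True  # 3-pixel blob
        assert not remove_small_objects(mask, min_pixels=5).any()

    def test_min_pixels_one_is_identity(self, rng):
        mask = rng.random((20, 20)) > 0.7
        np.testing.assert_array_equal(remove_small_objects(mask, min_pixels=1), mask)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            remove_small_objects(np.zeros((3, 3), dtype=bool), min_pixels=0)
        with pytest.raises(ValueError):
            remove_small_objects(np.zeros((3, 3), dtype=bool), connectivity=6)

    def _flood_sizes(self, mask, connectivity):
        # independent flood-fill component labeling oracle
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if connectivity == 8:
            offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        seen = np.zeros_like(mask, dtype=bool)
        sizes = []
        h, w = mask.shape
        for i in range(h):
            for j in range(w):
                if mask[i, j] and not seen[i, j]:
                    stack, size = [(i, j)], 0
                    seen[i, j] = True
                    while stack:
                        y, x = stack.pop()
                        size += 1
                        for dy, dx in offs:
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                    sizes.append(size)
        return sizes

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_surviving_components_verified_by_flood_fill(self, rng, connectivity):
        mask = rng.random((40, 40)) > 0.6
        out = remove_small_objects(mask, min_pixels=8, connectivity=connectivity)
        assert not np.any(out & ~mask)  # no pixel added
        sizes = self._flood_sizes(out, connectivity)
        assert all(s >= 8 for s in sizes)

    def test_monotone_in_min_pixels(self, rng):
        mask = rng.random((40, 40)) > 0.65
        prev = remove_small_objects(mask, min_pixels=1)
        for mp in (5, 10, 25, 60):
            cur = remove_small_objects(mask, min_pixels=mp)
            assert not np.any(cur & ~prev)
            prev = cur


class TestFovEstimation:
    def test_recovers_phantom_disc(self, phantom_noisy):
        est = estimate_fov_mask(phantom_noisy.image)
        agreement = np.mean(est == phantom_noisy.fov_mask)
        assert agreement >= 0.99

    def test_estimated_area_close_to_disc_area(self, phantom_noisy):
        est = estimate_fov_mask(phantom_noisy.image)
        true_area = phantom_noisy.fov_mask.sum()
        assert abs(est.sum() - true_area) / true_area <= 0.05

    def test_all_bright_image_gives_full_frame(self):
        img = np.full((32, 32, 3), 0.8)
        assert estimate_fov_mask(img).all()

    def test_all_dark_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_fov_mask(np.zeros((16, 16, 3)))


class TestExtractGreen:
    def test_projects_green_channel(self):
        img = np.zeros((2, 2, 3))
        img[0, 0] = (0.2, 0.7, 0.1)
        assert extract_green(img)[0, 0] == 0.7

    def test_pure_green_identity(self, rng):
        g = rng.random((8, 8))
        img = np.stack([np.zeros_like(g), g, np.zeros_like(g)], axis=-1)
        np.testing.assert_array_equal(extract_green(img), g)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            extract_green(np.zeros((4, 4)))


class TestSegmentVessels:
    def test_all_black_image_yields_empty_mask(self):
        assert not segment_vessels(np.zeros((128, 128, 3))).any()

    def test_noiseless_phantom_recovered(self, phantom_noiseless):
        mask = segment_vessels(
            phantom_noiseless.image, fov=phantom_noiseless.fov_mask
        )
        assert dice_coefficient(mask, phantom_noiseless.vessel_mask) >= 0.8

    def test_speckles_removed_by_small_object_filter(self, phantom_noiseless):
        sc = phantom_noiseless
        img = sc.image.copy()
        rng = np.random.default_rng(5)
        speckles = np.zeros(sc.vessel_mask.shape, dtype=bool)
        placed = 0
        while placed < 20:
            y, x = rng.integers(20, img.shape[0] - 20, size=2)
            if sc.fov_mask[y, x] and not sc.vessel_mask[y - 3 : y + 4, x - 3 : x + 4].any():
                # vessel-level brightness: subtle white spots, not saturated dots
                img[y, x : x + 2] = img[y, x : x + 2] + 0.12
                speckles[y, x : x + 2] = True
                placed += 1
        mask = segment_vessels(img, fov=sc.fov_mask, min_pixels=30)
        from skimage import measure

        labels = measure.label(mask, connectivity=2)
        speckle_components = np.unique(labels[speckles])
        for comp in speckle_components:
            if comp == 0:
                continue
            comp_mask = labels == comp
            # any surviving component touching a speckle must be a real vessel
            assert (comp_mask & sc.vessel_mask).sum() > 0

    def test_rotation_robustness_quarter_turn(self, phantom_noiseless):
        sc = phantom_noiseless
        m1 = segment_vessels(sc.image, fov=sc.fov_mask)
        m2 = segment_vessels(
            np.rot90(sc.image).copy(), fov=np.rot90(sc.fov_mask).copy()
        )
        back = np.rot90(m2, k=-1)
        assert dice_coefficient(m1, back) >= 0.95
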