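import numpy as np
import pytest

from scaffoldcontact import (
    ZStack,
    PhantomSpec,
    Fiber,
    adhoc_segment,
    binary_contact,
    contact_surface,
    fit_plane_points,
    fit_plane_wls,
    geometric_scaffold_segment,
    pooled_std,
    render_phantom,
    vesselness,
)
from scaffoldcontact.geometrical import PlaneFit, intensity_weights, plane_surface_mask


class TestPlaneFit:
    def test_exact_plane_recovered_with_zero_residual(self):
        vol = np.zeros((20, 16, 16))
        vol[10] = 1.0
        stack = ZStack(vol, (0.5, 0.1, 0.1))
        fit = fit_plane_wls(stack, vol, "upper")
        assert abs(fit.coeffs[2]) > 0.999  # normal is +z
        assert fit.coeffs[3] == pytest.approx(-10 * 0.5, abs=1e-9)
        assert fit.residual_std_nm == pytest.approx(0.0, abs=1e-6)

    def test_noisy_plane_residual_matches_injected_sigma(self, rng):
        n = 10_000
        pts = np.column_stack(
            [rng.uniform(0, 50, n), rng.uniform(0, 50, n), 5.0 + rng.normal(0, 0.1, n)]
        )  # 0.1 um = 100 nm perturbation along z
        fit = fit_plane_points(pts, np.ones(n))
        assert fit.residual_std_nm == pytest.approx(100.0, abs=15.0)

    def test_normal_recovered_within_one_degree(self, rng):
        true_normal = np.array([0.1, -0.05, 1.0])
        true_normal /= np.linalg.norm(true_normal)
        n = 5000
        xy = rng.uniform(0, 50, (n, 2))
        z = -(true_normal[0] * xy[:, 0] + true_normal[1] * xy[:, 1]) / true_normal[2]
        pts = np.column_stack([xy, z + rng.normal(0, 0.05, n)])
        fit = fit_plane_points(pts, np.ones(n))
        angle = np.degrees(np.arccos(np.clip(abs(fit.normal @ true_normal), 0, 1)))
        assert angle < 1.0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_plane_points(pts, np.ones(5))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_plane_points(np.zeros((2, 3)), np.ones(2))


class TestPooledStd:
    def _fit(self, n, std):
        return PlaneFit((0, 0, 1, 0), n_points=n, residual_std_nm=std)

    def test_identical_fits_pool_to_same_value(self):
        fits = [self._fit(100, 105.1) for _ in range(5)]
        assert pooled_std(fits) == pytest.approx(105.1)

    def test_hand_arithmetic_example(self):
        fits = [self._fit(3, 1.0), self._fit(3, 3.0)]
        assert pooled_std(fits) == pytest.approx(np.sqrt((2 * 1 + 2 * 9) / 4))

    def test_single_fit_reduces_to_its_residual(self):
        assert pooled_std([self._fit(50, 42.0)]) == pytest.approx(42.0)

    def test_insufficient_counts_rejected(self):
        with pytest.raises(ValueError):
            pooled_std([self._fit(1, 1.0)])


class TestVesselness:
    def test_constant_volume_gives_zero_response(self):
        assert not vesselness(np.full((10, 10, 10), 3.0), 1.5).any()

    def test_tube_beats_slab_at_equal_intensity(self):
        z, y, x = np.indices((32, 32, 32))
        tube = np.where((z - 16.0) ** 2 + (y - 16.0) ** 2 <= 4.0, 100.0, 0.0)
        slab = np.where(np.abs(z - 16) <= 2, 100.0, 0.0)
        assert vesselness(tube, 2.0).max() > vesselness(slab, 2.0).max()

    def test_response_peaks_on_the_cylinder_axis(self):
        z, y, x = np.indices((32, 32, 32))
        tube = np.where((z - 16.0) ** 2 + (y - 16.0) ** 2 <= 4.0, 100.0, 0.0)
        response = vesselness(tube, 2.0)
        zz, yy, _ = np.unravel_index(np.argmax(response), response.shape)
        assert abs(zz - 16) <= 1 and abs(yy - 16) <= 1

    def test_agrees_with_skimage_frangi_ordering_on_isotropic_volume(self, rng):
        """Independent cross-check: both implementations must enhance the
        tube far more than the surrounding background."""
        from skimage.filters import frangi

        z, y, x = np.indices((24, 24, 24))
        tube = np.where((z - 12.0) ** 2 + (y - 12.0) ** 2 <= 4.0, 100.0, 0.0)
        ours = vesselness(tube, 2.0)
        theirs = frangi(tube, sigmas=[2.0], black_ridges=False)
        axis = (slice(10, 14), slice(10, 14), slice(4, 20))
        for resp in (ours, theirs):
            assert resp[axis].max() > 10 * np.median(resp[resp > 0])


class TestAdhocSegment:
    def test_noiseless_fiber_recovered(self):
        spec = PhantomSpec(
            kind="fiber_bundle",
            fibers=[Fiber((8.0, 12.0, 0.0), (0, 0, 1), 5.0, 1000.0)],
            background_offset=100.0,
            noise_sigma=0.0,
            blur_sigma_um=(0, 0, 0),
            seed=0,
        )
        pair, truth = render_phantom(spec, (16, 24, 24), (1, 1, 1))
        mask = adhoc_segment(pair.scaffold)
        recall = (mask & truth["scaffold"]).sum() / truth["scaffold"].sum()
        assert recall >= 0.95

    def test_salt_noise_removed_by_filtering(self, rng):
        vol = np.full((16, 16, 16), 10.0)
        vol[2:14, 2:8, 2:8] = 1000.0  # one big block survives
        salt = rng.integers(0, 16, size=(10, 3))
        for z, y, x in salt:
            vol[z, (y + 9) % 16, (x + 9) % 16] = 1000.0  # isolated bright voxels
        mask = adhoc_segment(vol)
        # block interior survives (median filtering trims the block surface)
        assert mask[3:13, 3:7, 3:7].all()
        assert not mask[:, 9:, 9:].any()

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            adhoc_segment(np.full((8, 8, 8), 3.0))


class TestGeometricSegment:
    def test_spun_coat_surface_within_one_z_voxel(self, fixture_suite):
        pair, truth, spec = fixture_suite["spun_coat"]
        mask = geometric_scaffold_segment(pair.scaffold, "SC", "A6")
        zs = np.nonzero(mask)[0]
        true_top = np.nonzero(truth["scaffold"])[0].max()
        assert mask.any()
        assert np.all(np.abs(zs - true_top) <= 2)  # plane band is 1 voxel each side

    def test_sigma_matched_fiber_segmentation_beats_mismatched(self):
        # thin fiber (radius 1 voxel): sigma=1.0 is radius-matched
        spec = PhantomSpec(
            kind="fiber_bundle",
            fibers=[Fiber((2.88, 2.88, 0.0), (0, 0, 1), 0.12, 3000.0)],
            noise_sigma=10.0,
            seed=4,
            blur_sigma_um=(0.06, 0.06, 0.06),
        )
        pair, truth = render_phantom(spec, (48, 48, 48), (0.12, 0.12, 0.12))
        jac = {}
        for method in ("A6", "A7"):
            mask = geometric_scaffold_segment(pair.scaffold, "MF", method)
            assert mask.any()
            jac[method] = (mask & truth["scaffold"]).sum() / (mask | truth["scaffold"]).sum()
        assert jac["A6"] > jac["A7"]

    def test_empty_cell_mask_gives_empty_contact_region(self, fixture_suite):
        pair, _, _ = fixture_suite["single_fiber"]
        cell_mask = np.zeros(pair.shape, dtype=bool)
        mask = geometric_scaffold_segment(pair.scaffold, "MF", "A6", cell_mask=cell_mask)
        assert not mask.any()


class TestBinaryContact:
    def _brute_force(self, cell, scaffold):
        """Triple-loop oracle over all voxels and their 26-neighborhoods."""
        Z, Y, X = cell.shape
        out = np.zeros_like(cell)
        for z in range(Z):
            for y in range(Y):
                for x in range(X):
                    if not (cell[z, y, x] or scaffold[z, y, x]):
                        continue
                    nb = (slice(max(0, z - 1), z + 2), slice(max(0, y - 1), y + 2),
                          slice(max(0, x - 1), x + 2))
                    if cell[z, y, x] and scaffold[nb].any():
                        out[z, y, x] = True
                    if scaffold[z, y, x] and cell[nb].any():
                        out[z, y, x] = True
        return out

    def test_cooccurrence_single_voxel(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[4, 4, 4] = True
        np.testing.assert_array_equal(binary_contact(m, m), m)

    def test_adjacent_voxels_both_flagged(self):
        cell = np.zeros((12, 12, 12), dtype=bool)
        scaffold = np.zeros_like(cell)
        cell[5, 5, 5] = True
        scaffold[5, 5, 6] = True
        contact = binary_contact(cell, scaffold)
        assert contact[5, 5, 5] and contact[5, 5, 6]
        assert contact.sum() == 2

    def test_separated_masks_give_empty_contact(self):
        cell = np.zeros((10, 10, 10), dtype=bool)
        scaffold = np.zeros_like(cell)
        cell[2, 2, 2] = True
        scaffold[6, 6, 6] = True
        assert not binary_contact(cell, scaffold).any()

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(3):
            cell = rng.random((10, 10, 10)) > 0.8
            scaffold = rng.random((10, 10, 10)) > 0.8
            expected = self._brute_force(cell, scaffold)
            np.testing.assert_array_equal(binary_contact(cell, scaffold), expected)

    def test_symmetric_in_arguments(self, rng):
        cell = rng.random((8, 8, 8)) > 0.7
        scaffold = rng.random((8, 8, 8)) > 0.7
        np.testing.assert_array_equal(
            binary_contact(cell, scaffold), binary_contact(scaffold, cell)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_contact(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))


class TestContactSurface:
    def test_cube_surface_is_its_98_boundary_voxels(self):
        seg = np.zeros((9, 9, 9), dtype=bool)
        seg[2:7, 2:7, 2:7] = True
        surface = contact_surface(seg).mask
        # independent oracle: cube voxels minus the 3x3x3 interior
        expected = seg.copy()
        expected[3:6, 3:6, 3:6] = False
        np.testing.assert_array_equal(surface, expected)
        assert surface.sum() == 98

    def test_single_voxel_has_no_central_difference_support(self):
        seg = np.zeros((7, 7, 7), dtype=bool)
        seg[3, 3, 3] = True
        # the central-difference stencil is blind to an isolated voxel
        assert not contact_surface(seg).mask.any()

    def test_all_foreground_volume_has_no_interior_surface(self):
        surface = contact_surface(np.ones((6, 6, 6), dtype=bool)).mask
        assert not surface.any()

    def test_empty_segment_gives_empty_surface(self):
        assert not contact_surface(np.zeros((5, 5, 5), dtype=bool)).mask.any()
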