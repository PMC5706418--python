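import numpy as np
import pytest
from scipy import ndimage as ndi

from scaffoldcontact import (
    ZStack,
    ZStackPair,
    contact_probability,
    foreground_probability,
    kmeans_priors,
    max_entropy_threshold,
)
from scaffoldcontact.preprocessing import BackgroundModel
from scaffoldcontact.statistical import MODELS, ProbabilityVolume, estimate_bleed_coefficient


def _entropy_oracle(hist):
    """Exhaustive evaluation of the split-entropy criterion over all cuts."""
    hist = np.asarray(hist, float)

    def h(p):
        t = p.sum()
        if t == 0:
            return 0.0
        q = p[p > 0] / t
        return -(q * np.log(q)).sum()

    crits = [h(hist[:s]) + h(hist[s:]) for s in range(1, len(hist))]
    return int(np.argmax(crits)), crits


class TestMaxEntropyThreshold:
    def test_two_valued_volume_splits_the_modes(self):
        vol = np.full((4, 4, 4), 0.1)
        vol[2:] = 0.9
        _, mask = max_entropy_threshold(vol)
        np.testing.assert_array_equal(mask, vol == 0.9)

    def test_matches_exhaustive_oracle_on_known_histogram(self, rng):
        # realize a volume whose 8-bin histogram is exactly this
        counts = [5, 10, 20, 5, 0, 5, 20, 10]
        values = np.repeat(np.arange(8) + 0.5, counts) / 8.0  # bin centers in [0,1]
        vol = values.reshape(1, 1, -1)
        thr, _ = max_entropy_threshold(vol, n_bins=8)
        best_cut, crits = _entropy_oracle(counts)
        np.testing.assert_allclose(thr.criterion, crits)
        span = vol.max() - vol.min()
        expected_t = vol.min() + (best_cut + 1) * span / 8
        assert thr.t_opt == pytest.approx(expected_t)

    def test_matches_oracle_on_random_volumes(self, rng):
        for _ in range(5):
            vol = rng.random((6, 6, 6))
            thr, mask = max_entropy_threshold(vol, n_bins=32)
            hist, edges = np.histogram(vol, bins=32, range=(vol.min(), vol.max()))
            best_cut, crits = _entropy_oracle(hist)
            np.testing.assert_allclose(thr.criterion, crits)
            assert thr.t_opt == pytest.approx(edges[best_cut + 1])
            np.testing.assert_array_equal(mask, vol >= thr.t_opt)

    def test_translation_equivariance(self, rng):
        vol = rng.random((5, 5, 5))
        t0, _ = max_entropy_threshold(vol)
        t1, _ = max_entropy_threshold(vol + 10.0)
        bin_width = (vol.max() - vol.min()) / 256
        assert abs((t1.t_opt - 10.0) - t0.t_opt) <= bin_width

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="no valid threshold"):
            max_entropy_threshold(np.full((3, 3, 3), 2.0))


class TestForegroundModels:
    BKG = BackgroundModel(mean=100.0, std=10.0)

    def _two_level(self):
        vol = np.full((8, 16, 16), 100.0)
        vol[3:6, 4:12, 4:12] = 1000.0
        return ZStack(vol), vol >= 500

    def test_a1_is_half_at_background_mean(self):
        stack = ZStack(np.full((4, 4, 4), 100.0))
        stack.voxels[0, 0, 0] = 200.0  # break constancy
        p = foreground_probability(stack, self.BKG, "A1").values
        assert p[1, 1, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("model", MODELS)
    def test_two_level_phantom_separation(self, model):
        stack, fg = self._two_level()
        partner = ZStack(np.full(stack.shape, 100.0) + np.arange(stack.voxels.size)
                         .reshape(stack.shape) * 1e-3)
        p = foreground_probability(stack, self.BKG, model, partner=partner).values
        interior_fg = ndi.binary_erosion(fg, np.ones((1, 3, 3)))
        far_bg = ~ndi.binary_dilation(fg, np.ones((3, 3, 3)))
        assert p[interior_fg].min() > 0.99
        if model == "A1":
            # the Gaussian-tail rule sits at 0.5 on voxels at the background
            # mean by construction; separation, not absolute level
            assert p[far_bg].max() <= 0.5
        else:
            assert p[far_bg].max() < 0.01

    def test_a3_requires_partner(self):
        stack, _ = self._two_level()
        with pytest.raises(ValueError, match="partner"):
            foreground_probability(stack, self.BKG, "A3")

    def test_constant_stack_zero_std_warns_and_returns_zero(self):
        stack = ZStack(np.full((4, 4, 4), 5.0))
        with pytest.warns(UserWarning):
            p = foreground_probability(stack, BackgroundModel(5.0, 0.0), "A1")
        assert not p.values.any()

    def test_bleed_coefficient_recovered_on_phantom(self, fixture_suite):
        pair, truth, spec = fixture_suite["bleed_through"]
        from scaffoldcontact.preprocessing import estimate_background

        cb = estimate_background(pair.cell)
        sb = estimate_background(pair.scaffold)
        alpha = estimate_bleed_coefficient(
            pair.scaffold.voxels.astype(float), pair.cell.voxels.astype(float), sb, cb
        )
        assert alpha == pytest.approx(spec.bleed_alpha, abs=0.05)


class TestKMeansPriors:
    def _cloud_pair(self, rng, n=1500, spread=5.0):
        clouds = np.concatenate(
            [
                rng.normal([100, 100], spread, (n, 2)),   # background
                rng.normal([3000, 150], spread, (n, 2)),  # cell
                rng.normal([120, 2500], spread, (n, 2)),  # scaffold
            ]
        )
        cell = clouds[:, 0].reshape(3, n, 1)
        scaffold = clouds[:, 1].reshape(3, n, 1)
        labels = np.repeat(["P(BKG)", "P(Cell)", "P(Scaffold)"], n)
        return ZStackPair(ZStack(cell), ZStack(scaffold)), labels

    def test_well_separated_clouds_get_majority_probability(self, rng):
        pair, labels = self._cloud_pair(rng)
        model, priors = kmeans_priors(pair)
        stacked = np.stack([priors[k].ravel() for k in ("P(BKG)", "P(Cell)", "P(Scaffold)")])
        majority = np.array(["P(BKG)", "P(Cell)", "P(Scaffold)"])[np.argmax(stacked, axis=0)]
        assert (majority == labels).mean() >= 0.99

    def test_probabilities_sum_to_one_everywhere(self, rng):
        pair, _ = self._cloud_pair(rng, n=400)
        _, priors = kmeans_priors(pair)
        total = sum(priors.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_voxel_at_centroid_gets_probability_one(self, rng):
        pair, _ = self._cloud_pair(rng, n=400)
        model, priors = kmeans_priors(pair)
        # plant one voxel exactly on the cell centroid
        cell_c = model.centroids[1]
        cv = pair.cell.voxels.copy()
        sv = pair.scaffold.voxels.copy()
        cv[0, 0, 0], sv[0, 0, 0] = cell_c
        pair2 = ZStackPair(ZStack(cv), ZStack(sv))
        model2, priors2 = kmeans_priors(pair2)
        if np.allclose(model2.centroids, model.centroids, atol=1.0):
            assert priors2["P(Cell)"][0, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_equidistant_point_gets_uniform_probabilities(self):
        # symmetric three-cloud configuration around the probe point
        base = np.array([[0.0, 0.0], [200.0, 0.0], [100.0, 173.2]])
        pts = np.concatenate([np.tile(row, (50, 1)) + np.arange(50)[:, None] * 1e-3
                              for row in base])
        probe = base.mean(axis=0)  # equidistant from all three centroids
        pts = np.vstack([pts, probe])
        cell = pts[:, 0].reshape(1, 1, -1)
        scaffold = pts[:, 1].reshape(1, 1, -1)
        _, priors = kmeans_priors(ZStackPair(ZStack(cell), ZStack(scaffold)))
        for key in priors:
            assert priors[key][0, 0, -1] == pytest.approx(1 / 3, abs=0.01)

    def test_too_few_distinct_intensity_pairs_rejected(self):
        pair = ZStackPair(ZStack(np.zeros((2, 2, 2))), ZStack(np.zeros((2, 2, 2))))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_priors(pair)


class TestContactProbability:
    def _priors(self, shape, rng):
        a = rng.random(shape)
        b = rng.random(shape) * (1 - a)
        return {"P(Cell)": a, "P(Scaffold)": b, "P(BKG)": 1 - a - b}

    def test_zero_conditionals_give_zero_contact(self, rng):
        shape = (3, 3, 3)
        zero = ProbabilityVolume(np.zeros(shape))
        p = contact_probability(zero, zero, self._priors(shape, rng))
        assert not p.values.any()

    def test_unit_conditionals_give_one_minus_background(self, rng):
        shape = (3, 3, 3)
        one = ProbabilityVolume(np.ones(shape))
        priors = self._priors(shape, rng)
        p = contact_probability(one, one, priors)
        np.testing.assert_allclose(p.values, 1 - priors["P(BKG)"], atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        shape = (3, 4, 2)
        pc = ProbabilityVolume(rng.random(shape))
        ps = ProbabilityVolume(rng.random(shape))
        priors = self._priors(shape, rng)
        result = contact_probability(pc, ps, priors).values
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    expected = (
                        pc.values[z, y, x] * priors["P(Cell)"][z, y, x]
                        + ps.values[z, y, x] * priors["P(Scaffold)"][z, y, x]
                    )
                    assert result[z, y, x] == pytest.approx(expected)

    def test_bounded_by_one_minus_background_prior(self, rng):
        shape = (4, 4, 4)
        pc = ProbabilityVolume(rng.random(shape))
        ps = ProbabilityVolume(rng.random(shape))
        priors = self._priors(shape, rng)
        p = contact_probability(pc, ps, priors).values
        assert np.all(p <= 1 - priors["P(BKG)"] + 1e-12)

    def test_shape_mismatch_rejected(self, rng):
        pc = ProbabilityVolume(np.zeros((2, 2, 2)))
        ps = ProbabilityVolume(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            contact_probability(pc, ps, self._priors((2, 2, 2), rng))
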