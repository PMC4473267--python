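"""Spatial GMM filtering: EM oracles, pruning rules, reconstruction."""

import numpy as np
import pytest

from datnorm.fgmm import (
    PruneConfig,
    SpatialGMM,
    fgmm_normalize,
    fit_spatial_gmm,
    prune_clusters,
    reconstruct,
    uniform_threshold,
)
from datnorm.volume_io import BinaryMask, Volume, mask_mean


def _gaussian_blob(shape, center, sigma, amplitude=1.0):
    grids = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma))
    return amplitude * np.exp(-0.5 * d2)


def weighted_moments(volume):
    """Independent closed-form oracle: intensity-weighted mean/covariance."""
    data = volume.data
    flat = data.ravel()
    pos = np.flatnonzero(flat > 0)
    pts = np.column_stack(np.unravel_index(pos, data.shape)).astype(float)
    w = flat[pos] / flat[pos].sum()
    mu = w @ pts
    diff = pts - mu
    cov = (diff * w[:, None]).T @ diff
    return mu, cov


class TestUniformThreshold:
    def test_canonical_grid(self):
        eta = uniform_threshold((73, 73, 45))
        assert eta == pytest.approx(1.0 / 239805)
        # one significant figure: 4e-6
        assert float(f"{eta:.0e}") == 4e-6

    @pytest.mark.parametrize(
        "shape,expected", [((1, 1, 1), 1.0), ((10, 10, 10), 1e-3)]
    )
    def test_small_grids(self, shape, expected):
        assert uniform_threshold(shape) == pytest.approx(expected)


class TestFit:
    def test_k1_equals_weighted_moments(self, rng):
        data = rng.gamma(2.0, 1.0, size=(12, 11, 9))
        vol = Volume(data)
        model = fit_spatial_gmm(vol, k=1, seed=0)
        mu, cov = weighted_moments(vol)
        np.testing.assert_allclose(model.means[0], mu, rtol=1e-6)
        np.testing.assert_allclose(model.covariances[0], cov, rtol=1e-6)
        assert model.weights[0] == pytest.approx(1.0)
        assert model.total_intensity == pytest.approx(data.sum())

    def test_single_blob_center_recovered(self):
        vol = Volume(_gaussian_blob((21, 21, 15), (9.5, 11.0, 7.0), (2.0, 2.5, 1.8)))
        model = fit_spatial_gmm(vol, k=1, seed=0)
        assert np.abs(model.means[0] - np.array([9.5, 11.0, 7.0])).max() < 0.5

    def test_seeded_determinism(self, rng):
        vol = Volume(rng.gamma(2.0, 1.0, size=(10, 10, 8)))
        a = fit_spatial_gmm(vol, k=4, seed=7)
        b = fit_spatial_gmm(vol, k=4, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.covariances, b.covariances)

    def test_weights_normalized_after_fit(self, rng):
        vol = Volume(rng.gamma(2.0, 1.0, size=(10, 10, 8)))
        model = fit_spatial_gmm(vol, k=5, seed=1)
        assert model.weights.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(model.weights >= 0)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_spatial_gmm(Volume(np.zeros((4, 4, 4))), k=1)

    def test_k_exceeding_positive_voxels_rejected(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = data[1, 1, 1] = 1.0
        with pytest.raises(ValueError, match="exceeds"):
            fit_spatial_gmm(Volume(data), k=3)


class TestPrune:
    def _two_blob_setup(self):
        """One blob inside the striatal region, one far outside."""
        shape = (24, 24, 16)
        inside = _gaussian_blob(shape, (6.0, 6.0, 8.0), (1.5, 1.5, 1.5), 5.0)
        outside = _gaussian_blob(shape, (18.0, 18.0, 8.0), (1.5, 1.5, 1.5), 5.0)
        vol = Volume(inside + outside)
        sr = np.zeros(shape, bool)
        sr[3:10, 3:10, 5:12] = True
        return vol, BinaryMask(sr)

    def test_out_of_region_component_pruned(self):
        vol, sr = self._two_blob_setup()
        model = fit_spatial_gmm(vol, k=2, seed=0)
        eta = uniform_threshold(vol.shape)
        pruned = prune_clusters(model, sr, PruneConfig(eta=eta))
        # brute force: evaluate each component density over all SR voxels
        coords = sr.coordinates()
        expected_zero = []
        for n in range(2):
            f = np.exp(model.component_log_density(n, coords))
            expected_zero.append((f < eta).mean() >= 0.75)
        assert sum(expected_zero) == 1
        np.testing.assert_array_equal(pruned.weights == 0.0, expected_zero)

    def test_retained_weights_not_renormalized(self):
        vol, sr = self._two_blob_setup()
        model = fit_spatial_gmm(vol, k=2, seed=0)
        pruned = prune_clusters(model, sr, PruneConfig(eta=uniform_threshold(vol.shape)))
        kept = pruned.weights > 0
        np.testing.assert_array_equal(pruned.weights[kept], model.weights[kept])
        assert pruned.grid_norm == model.grid_norm

    def test_density_exactly_at_threshold_retained(self):
        """The irrelevance rule uses a strict inequality."""
        vol, _ = self._two_blob_setup()
        model = fit_spatial_gmm(vol, k=1, seed=0)
        single = np.zeros(vol.shape, bool)
        single[6, 6, 8] = True
        sr = BinaryMask(single)
        f_at = float(np.exp(model.component_log_density(0, sr.coordinates()))[0])
        pruned = prune_clusters(model, sr, PruneConfig(eta=f_at))
        assert pruned.weights[0] > 0  # f == eta does not count as below

    def test_raising_eta_prunes_monotonically(self):
        vol, sr = self._two_blob_setup()
        model = fit_spatial_gmm(vol, k=4, seed=3)
        etas = [1e-9, 1e-6, 1e-3, 1e-1]
        pruned_sets = []
        for eta in etas:
            pruned = prune_clusters(model, sr, PruneConfig(eta=eta))
            pruned_sets.append(frozenset(np.flatnonzero(pruned.weights == 0)))
        for small, large in zip(pruned_sets, pruned_sets[1:]):
            assert small <= large


class TestReconstruct:
    def test_unpruned_reconstruction_conserves_total(self, rng):
        vol = Volume(rng.gamma(2.0, 1.0, size=(14, 12, 10)))
        model = fit_spatial_gmm(vol, k=3, seed=2)
        rec = reconstruct(model)
        assert rec.data.sum() == pytest.approx(model.total_intensity, rel=1e-10)

    def test_pruning_is_pointwise_monotone(self):
        shape = (24, 24, 16)
        vol = Volume(
            _gaussian_blob(shape, (6, 6, 8), (2, 2, 2), 5.0)
            + _gaussian_blob(shape, (18, 18, 8), (2, 2, 2), 5.0)
        )
        sr = np.zeros(shape, bool)
        sr[3:10, 3:10, 5:12] = True
        model = fit_spatial_gmm(vol, k=2, seed=0)
        full = reconstruct(model)
        pruned = reconstruct(
            prune_clusters(model, BinaryMask(sr), PruneConfig(eta=uniform_threshold(shape)))
        )
        assert np.all(pruned.data <= full.data + 1e-15)

    def test_all_weights_zero_gives_zero_volume(self, rng):
        vol = Volume(rng.gamma(2.0, 1.0, size=(8, 8, 6)))
        model = fit_spatial_gmm(vol, k=2, seed=0)
        model.weights[:] = 0.0
        np.testing.assert_array_equal(reconstruct(model).data, 0.0)


class TestNormalizePipeline:
    def test_striatal_intensity_preserved_background_suppressed(
        self, phantom_cohort, phantom_assets
    ):
        cohort, _ = phantom_cohort
        _, masks = phantom_assets
        vol = cohort.volumes[0]
        model = fit_spatial_gmm(vol, k=8, seed=5)
        full = reconstruct(model)
        pruned = reconstruct(
            prune_clusters(
                model, masks.striatal, PruneConfig(eta=uniform_threshold(vol.shape))
            )
        )
        sr_ratio = mask_mean(pruned, masks.striatal) / mask_mean(full, masks.striatal)
        ns_ratio = mask_mean(pruned, masks.nonspecific) / mask_mean(full, masks.nonspecific)
        assert sr_ratio >= 0.85
        assert ns_ratio < 1.0

    def test_fgmm_normalize_deterministic(self, phantom_cohort, phantom_assets):
        cohort, _ = phantom_cohort
        _, masks = phantom_assets
        out1 = fgmm_normalize(cohort.volumes[0], masks.striatal, k=4, seed=9)
        out2 = fgmm_normalize(cohort.volumes[0], masks.striatal, k=4, seed=9)
        np.testing.assert_array_equal(out1.data, out2.data)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        vol = Volume(rng.gamma(2.0, 1.0, size=(8, 8, 6)))
        model = fit_spatial_gmm(vol, k=3, seed=4)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SpatialGMM.from_json(path)
        np.testing.assert_allclose(back.weights, model.weights, rtol=1e-15)
        np.testing.assert_allclose(back.means, model.means, rtol=1e-15)
        np.testing.assert_allclose(back.covariances, model.covariances, rtol=1e-15)
        assert back.shape == model.shape
        assert back.grid_norm == model.grid_norm
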