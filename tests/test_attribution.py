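import numpy as np
import pytest
from scipy import stats

from latentevo.attribution import (AttributionMask, FilterBankExtractor,
                                   compare_mask_correlations,
                                   concentration_score, extract_local_features,
                                   feature_exemplar, mask_correlation,
                                   mask_weight_vector,
                                   perceptual_similarity_map,
                                   spatial_attribution_mask, total_variation)


@pytest.fixture(scope="module")
def extractor():
    return FilterBankExtractor(patch_size=8, stride=4, channels=12, seed=1)


def random_images(rng, n, size=32):
    return rng.uniform(0, 1, size=(n, size, size, 3))


class TestExtractor:
    def test_constant_images_give_constant_maps(self, extractor):
        grid = extract_local_features(np.full((2, 32, 32, 3), 0.5), extractor)
        for img_feats in grid.values:
            flat = img_feats.reshape(-1, grid.channels)
            assert np.abs(flat - flat[0]).max() < 1e-10

    def test_output_shape_contract(self, extractor):
        rng = np.random.default_rng(0)
        grid = extract_local_features(random_images(rng, 3), extractor)
        gh, gw = extractor.grid_shape(32, 32)
        assert grid.values.shape == (3, gh, gw, 12)

    def test_translation_by_one_stride_shifts_one_cell(self, extractor):
        rng = np.random.default_rng(1)
        base = np.full((32, 32, 3), 0.5)
        patch = rng.uniform(0, 1, size=(8, 8, 3))
        a = base.copy()
        a[8:16, 8:16] = patch
        b = base.copy()
        b[8:16, 12:20] = patch        # shifted by one stride in x
        fa = extract_local_features(a[None], extractor).values[0]
        fb = extract_local_features(b[None], extractor).values[0]
        np.testing.assert_allclose(fb[:, 1:, :], fa[:, :-1, :], atol=1e-10)

    def test_mismatched_sizes_rejected(self, extractor):
        with pytest.raises(ValueError):
            extractor(np.zeros((1, 4, 4, 3)))


class TestAttributionMask:
    def test_noiseless_linear_readout_r2_one(self, extractor):
        rng = np.random.default_rng(2)
        images = random_images(rng, 120)
        grid = extract_local_features(images, extractor)
        ci, cj = 3, 4
        w = rng.normal(size=grid.channels)
        responses = grid.values[:, ci, cj, :] @ w + 5.0
        mask = spatial_attribution_mask(grid, responses)
        assert mask.r2[ci, cj] == pytest.approx(1.0, abs=1e-8)
        assert np.unravel_index(np.argmax(mask.adj_r2),
                                mask.adj_r2.shape) == (ci, cj)

    def test_pure_noise_adjusted_r2_near_zero(self):
        extractor = FilterBankExtractor(patch_size=8, stride=4, channels=16,
                                        seed=2)
        rng = np.random.default_rng(3)
        images = random_images(rng, 200)
        grid = extract_local_features(images, extractor)
        responses = rng.normal(size=200)
        mask = spatial_attribution_mask(grid, responses)
        assert abs(mask.adj_r2.mean()) < 0.05

    def test_duplicated_dataset_unchanged(self, extractor):
        rng = np.random.default_rng(4)
        images = random_images(rng, 60)
        grid = extract_local_features(images, extractor)
        responses = rng.normal(size=60)
        m1 = spatial_attribution_mask(grid, responses)
        grid2 = extract_local_features(np.concatenate([images, images]),
                                       extractor)
        m2 = spatial_attribution_mask(grid2, np.concatenate([responses,
                                                             responses]))
        np.testing.assert_allclose(m1.r2, m2.r2, atol=1e-8)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-6)

    def test_constant_responses_flagged(self, extractor):
        rng = np.random.default_rng(5)
        grid = extract_local_features(random_images(rng, 30), extractor)
        mask = spatial_attribution_mask(grid, np.full(30, 7.0))
        assert mask.flags.get("constant_responses")
        assert np.all(mask.r2 == 0)

    def test_ridge_fallback_flagged(self, extractor):
        rng = np.random.default_rng(6)
        grid = extract_local_features(random_images(rng, 10), extractor)
        mask = spatial_attribution_mask(grid, rng.normal(size=10))
        assert mask.flags.get("ridge_fallback")


def make_mask(adj_r2, weights=None):
    gh, gw = adj_r2.shape
    if weights is None:
        weights = np.arange(gh * gw * 2, dtype=float).reshape(gh, gw, 2)
    return AttributionMask(adj_r2, adj_r2.copy(), weights, 100)


class TestMaskWeightVector:
    def test_single_hot_cell(self):
        adj = np.array([[0.0, 0.1], [0.2, 1.0]])
        mask = make_mask(adj)
        np.testing.assert_array_equal(mask_weight_vector(mask),
                                      mask.weights[1, 1])

    def test_largest_region_wins(self):
        adj = np.full((6, 6), 0.05)
        adj[0, 0:5] = 0.9            # 5-cell region
        adj[4:6, 0] = 0.9            # 3-cell region (with (5,1))
        adj[5, 1] = 0.9
        mask = make_mask(adj)
        expected = mask.weights[0, 0:5].mean(axis=0)
        np.testing.assert_allclose(mask_weight_vector(mask, percentile=70),
                                   expected)

    def test_tie_breaks_row_major(self):
        adj = np.full((6, 6), 0.05)
        adj[1, 1:3] = 0.9
        adj[4, 3:5] = 0.9            # same size, later in row-major order
        mask = make_mask(adj)
        expected = mask.weights[1, 1:3].mean(axis=0)
        np.testing.assert_allclose(mask_weight_vector(mask, percentile=80),
                                   expected)


class TestMaskCorrelation:
    def test_identical_and_negated(self):
        v = np.array([1.0, 2.0, -1.0, 0.5])
        assert mask_correlation(v, v) == pytest.approx(1.0)
        assert mask_correlation(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_centered_vectors(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert mask_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_nan(self):
        assert np.isnan(mask_correlation(np.ones(4), np.arange(4.0)))

    def test_shared_locus_neurons_correlate(self, extractor):
        """Same-driver weight vectors beat cross-driver ones (rank test)."""
        rng = np.random.default_rng(7)
        gh, gw = extractor.grid_shape(32, 32)

        def weight_vec(ci, cj, w, seed):
            r = np.random.default_rng(seed)
            images = random_images(r, 200)
            grid = extract_local_features(images, extractor)
            signal = grid.values[:, ci, cj, :] @ w
            responses = signal + r.normal(0, 0.2 * signal.std(), size=200)
            return mask_weight_vector(spatial_attribution_mask(grid, responses))

        same, cross = [], []
        for k in range(12):
            w = rng.normal(size=extractor.channels)
            ci, cj = rng.integers(1, gh - 1), rng.integers(1, gw - 1)
            va = weight_vec(ci, cj, w, 100 + k)
            vb = weight_vec(ci, cj, w, 200 + k)
            w2 = rng.normal(size=extractor.channels)
            ci2, cj2 = rng.integers(1, gh - 1), rng.integers(1, gw - 1)
            vc = weight_vec(ci2, cj2, w2, 300 + k)
            same.append(mask_correlation(va, vb))
            cross.append(mask_correlation(va, vc))
        res = compare_mask_correlations(same, cross)
        assert res["same_mean"] > res["cross_mean"]
        assert res["p"] < 0.05


class TestTotalVariation:
    def test_constant_map_zero(self):
        assert total_variation(np.full((7, 9), 3.0)) == 0.0

    def test_unit_step_across_column(self):
        n = 6
        arr = np.zeros((n, 8))
        arr[:, 4:] = 1.0
        assert total_variation(arr) == pytest.approx(n)

    def test_homogeneity(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(size=(10, 10))
        assert total_variation(3.5 * arr) == pytest.approx(
            3.5 * total_variation(arr))

    def test_smoother_masks_from_structured_sessions(self):
        """Successful (structured) sessions yield lower-TV masks than null.

        Maps are range-normalized first so the comparison is about spatial
        cohesion, not about the absolute R2 scale.
        """
        extractor = FilterBankExtractor(patch_size=8, stride=4, channels=8,
                                        seed=3)
        rng = np.random.default_rng(9)

        def norm_tv(mask):
            m = mask.adj_r2 - mask.adj_r2.min()
            return total_variation(m / m.max())

        tv_success, tv_null = [], []
        for k in range(8):
            images = random_images(np.random.default_rng(500 + k), 100)
            grid = extract_local_features(images, extractor)
            w = rng.normal(size=8)
            resp = grid.values[:, 3, 3, :] @ w
            resp_noise = rng.normal(size=100) * resp.std()
            m_s = spatial_attribution_mask(grid, resp + 0.2 * resp_noise)
            m_n = spatial_attribution_mask(grid, resp_noise)
            tv_success.append(norm_tv(m_s))
            tv_null.append(norm_tv(m_n))
        assert stats.ranksums(tv_success, tv_null).pvalue < 0.05
        assert np.median(tv_success) < np.median(tv_null)


class TestSimilarityHeatmap:
    def test_identical_images_similarity_one(self, extractor):
        rng = np.random.default_rng(10)
        img = random_images(rng, 1)[0]
        heat = perceptual_similarity_map(img, img, extractor)
        np.testing.assert_allclose(heat.values, 1.0)

    def test_symmetry(self, extractor):
        rng = np.random.default_rng(11)
        a, b = random_images(rng, 2)
        h1 = perceptual_similarity_map(a, b, extractor)
        h2 = perceptual_similarity_map(b, a, extractor)
        np.testing.assert_allclose(h1.values, h2.values)

    def test_bounded_above_by_one(self, extractor):
        rng = np.random.default_rng(12)
        a, b = random_images(rng, 2)
        assert perceptual_similarity_map(a, b, extractor).values.max() <= 1.0

    def test_shared_quadrant_concentrates_similarity(self, extractor):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(40 + seed)
            a, b = random_images(rng, 2)
            a[16:, 16:] = b[16:, 16:]          # shared bottom-right quadrant
            heat = perceptual_similarity_map(a, b, extractor).values
            thresh = np.quantile(heat, 0.9)
            hot = np.argwhere(heat >= thresh)
            gh, gw = heat.shape
            in_quad = np.mean((hot[:, 0] >= gh // 2) & (hot[:, 1] >= gw // 2))
            hits.append(in_quad)
        assert np.mean([h >= 0.7 for h in hits]) >= 0.8

    def test_size_mismatch_rejected(self, extractor):
        with pytest.raises(ValueError):
            perceptual_similarity_map(np.zeros((32, 32, 3)),
                                      np.zeros((16, 16, 3)), extractor)


class TestConcentrationScore:
    def test_uniform_map(self):
        assert concentration_score(np.full((10, 10), 0.3),
                                   sizes=(1, 2, 3)) == pytest.approx(0.3)

    def test_delta_map(self):
        arr = np.zeros((9, 9))
        arr[4, 4] = 1.0
        assert concentration_score(arr, sizes=(1, 2)) == pytest.approx(0.625)

    def test_translation_invariance_away_from_borders(self):
        rng = np.random.default_rng(13)
        pattern = rng.uniform(0, 1, size=(3, 3))
        scores = []
        for (r, c) in [(4, 4), (4, 8), (8, 4), (8, 8)]:
            arr = np.zeros((16, 16))
            arr[r:r + 3, c:c + 3] = pattern
            scores.append(concentration_score(arr, sizes=(1, 2, 3)))
        np.testing.assert_allclose(scores, scores[0])

    def test_oversized_filter_rejected(self):
        with pytest.raises(ValueError):
            concentration_score(np.zeros((4, 4)), sizes=(5,))


class TestLocalization:
    def test_planted_cell_recovered(self):
        extractor = FilterBankExtractor(patch_size=8, stride=4, channels=8,
                                        seed=4)
        gh, gw = extractor.grid_shape(32, 32)
        hits = 0
        runs = 5
        for seed in range(runs):
            rng = np.random.default_rng(700 + seed)
            images = random_images(rng, 300)
            grid = extract_local_features(images, extractor)
            ci, cj = rng.integers(1, gh - 1), rng.integers(1, gw - 1)
            w = rng.normal(size=8)
            resp = grid.values[:, ci, cj, :] @ w
            resp += rng.normal(0, 0.1 * resp.std(), size=300)
            mask = spatial_attribution_mask(grid, resp)
            hits += (np.unravel_index(np.argmax(mask.adj_r2),
                                      mask.adj_r2.shape) == (ci, cj))
        assert hits >= runs - 1


class TestFeatureExemplar:
    def test_planted_readout_recovery_and_maximization(self, object_gen):
        extractor = FilterBankExtractor(patch_size=8, stride=4, channels=8,
                                        seed=5)
        rng = np.random.default_rng(14)
        gh, gw = extractor.grid_shape(32, 32)
        latents = rng.normal(scale=0.25, size=(500, object_gen.latent_dim))
        images = object_gen.render_batch(latents)
        grid = extract_local_features(images, extractor)
        s_true = np.exp(-((np.arange(gh)[:, None] - 3) ** 2
                          + (np.arange(gw)[None, :] - 3) ** 2) / 4.0)
        c_true = rng.normal(size=8)
        signal = np.einsum("nijc,ij,c->n", grid.values, s_true, c_true)
        responses = signal + rng.normal(0, 0.1 * signal.std(), size=500)

        result = feature_exemplar(images, responses, extractor, object_gen,
                                  seed=0, generations=40, popsize=16)
        planted = np.outer(s_true.ravel(),
                           c_true)[None].ravel()
        fitted = np.outer(result.spatial_weights.ravel(),
                          result.channel_weights).ravel()
        corr = np.corrcoef(planted.ravel(), fitted)[0, 1]
        assert abs(corr) >= 0.9
        train_preds = result.predict(images)
        assert result.predicted_response >= train_preds.max() - 1e-9

    def test_seed_determinism(self, object_gen):
        extractor = FilterBankExtractor(patch_size=8, stride=4, channels=8,
                                        seed=5)
        rng = np.random.default_rng(15)
        latents = rng.normal(scale=0.25, size=(60, object_gen.latent_dim))
        images = object_gen.render_batch(latents)
        grid = extract_local_features(images, extractor)
        responses = grid.values[:, 2, 2, :].sum(axis=1)
        a = feature_exemplar(images, responses, extractor, object_gen, seed=3,
                             generations=5, popsize=8)
        b = feature_exemplar(images, responses, extractor, object_gen, seed=3,
                             generations=5, popsize=8)
        np.testing.assert_array_equal(a.image, b.image)

    def test_too_few_pairs_rejected(self, object_gen):
        with pytest.raises(ValueError):
            feature_exemplar(np.zeros((10, 32, 32, 3)), np.zeros(10),
                             None, object_gen)

    def test_degenerate_screen_rejected(self, object_gen, extractor):
        rng = np.random.default_rng(16)
        images = np.full((60, 32, 32, 3), 0.5)
        with pytest.raises(ValueError, match="screen"):
            feature_exemplar(images, rng.normal(size=60), extractor,
                             object_gen, seed=0)
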