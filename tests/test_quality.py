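"""Sharpness, SSIM and the trained block-statistics quality model."""

import numpy as np
import pytest

import deglare as dg
from deglare.quality import extract_block_features, load_model, save_model


class TestSharpness:
    def test_constant_image_is_zero(self):
        assert dg.sharpness(np.full((32, 32), 0.7)).scalar == 0.0

    def test_unit_ramp_has_unit_gradient(self):
        image = np.tile(np.arange(32, dtype=float), (32, 1))
        assert dg.sharpness(image).scalar == pytest.approx(1.0, abs=1e-9)

    def test_degradation_reduces_sharpness(self, star, degraded_stars):
        assert dg.sharpness(degraded_stars[5.0]).scalar < dg.sharpness(star).scalar

    def test_transpose_invariant_and_nonnegative(self):
        rng = np.random.default_rng(0)
        image = rng.random((24, 24))
        s = dg.sharpness(image)
        assert np.all(s.values >= 0)
        assert dg.sharpness(image.T).scalar == pytest.approx(s.scalar, rel=1e-12)

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError):
            dg.sharpness(np.ones((1, 1)))


def uniform_ssim_oracle(a, b, win=3, k1=0.01, k2=0.03):
    """Sliding uniform-window SSIM with sample covariance (independent oracle)."""
    c1, c2 = (k1 * 1.0) ** 2, (k2 * 1.0) ** 2
    h, w = a.shape
    r = win // 2
    values = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            pa = a[i - r : i + r + 1, j - r : j + r + 1].ravel()
            pb = b[i - r : i + r + 1, j - r : j + r + 1].ravel()
            mua, mub = pa.mean(), pb.mean()
            va = pa.var(ddof=1)
            vb = pb.var(ddof=1)
            cov = ((pa - mua) * (pb - mub)).sum() / (pa.size - 1)
            values.append(
                ((2 * mua * mub + c1) * (2 * cov + c2))
                / ((mua**2 + mub**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(values))


class TestSSIM:
    def test_identity_is_one(self):
        rng = np.random.default_rng(1)
        image = rng.random((32, 32))
        assert dg.ssim(image, image).index == pytest.approx(1.0, abs=1e-9)

    def test_inversion_lowers_index(self):
        rng = np.random.default_rng(2)
        image = rng.random((32, 32))
        assert dg.ssim(1.0 - image, image).index < 1.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((24, 24)), rng.random((24, 24))
        fwd = dg.ssim(a, b).index
        assert fwd == pytest.approx(dg.ssim(b, a).index, abs=1e-12)
        assert -1.0 <= fwd <= 1.0

    def test_matches_uniform_window_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        mine = dg.ssim(a, b, gaussian_window=False, win_size=3).index
        assert mine == pytest.approx(uniform_ssim_oracle(a, b, win=3), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dg.ssim(np.ones((8, 8)), np.ones((9, 9)))


class TestBlockFeatures:
    def test_block_count_400_over_40(self, star):
        blocks = extract_block_features(star, 40, selection_percentile=0)
        assert blocks.n_blocks_total == 100
        assert blocks.features.shape == (100, 3)

    def test_constant_image_blocks(self):
        blocks = extract_block_features(
            np.full((80, 80), 0.3), 40, selection_percentile=0
        )
        np.testing.assert_allclose(blocks.features[:, 0], 0.3)
        np.testing.assert_allclose(blocks.features[:, 1], 0.0, atol=1e-15)
        np.testing.assert_allclose(blocks.features[:, 2], 0.0, atol=1e-15)

    def test_checkerboard_blocks_identical(self):
        tile = np.kron(np.indices((80, 80)).sum(axis=0) % 2, np.ones((1, 1)))
        blocks = extract_block_features(tile.astype(float), 40,
                                        selection_percentile=0)
        assert blocks.features.shape[0] == 4
        for row in blocks.features[1:]:
            np.testing.assert_allclose(row, blocks.features[0], atol=1e-12)

    def test_tiny_block_size_rejected(self):
        with pytest.raises(ValueError):
            extract_block_features(np.ones((8, 8)), 1)


class TestNIQEModel:
    def test_mean_equals_pooled_block_mean(self, star):
        model = dg.train_niqe([star], 40)
        features = extract_block_features(star, 40).features
        np.testing.assert_allclose(
            model.mean_vector, features.mean(axis=0), atol=1e-12
        )

    def test_duplicated_references_leave_model_unchanged(self, star):
        single = dg.train_niqe([star], 40)
        triple = dg.train_niqe([star, star, star], 40)
        np.testing.assert_allclose(single.mean_vector, triple.mean_vector)
        np.testing.assert_allclose(
            single.covariance_matrix, triple.covariance_matrix
        )

    def test_reference_order_irrelevant(self):
        refs, _ = dg.make_fixture_set(3, 1, seed=0, size=120)
        image = dg.siemens_star(dg.StarSpec(size=120, n_spokes=16))
        fwd = dg.niqe_score(image, dg.train_niqe(refs, 40))
        rev = dg.niqe_score(image, dg.train_niqe(refs[::-1], 40))
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_self_score_is_zero(self, star):
        model = dg.train_niqe([star], 40)
        assert dg.niqe_score(star, model) == pytest.approx(0.0, abs=1e-9)

    def test_scores_are_nonpositive(self, star, degraded_stars, niqe_model):
        for image in (star, degraded_stars[2.0]):
            assert dg.niqe_score(np.clip(image, 0, 1), niqe_model) <= 0.0

    def test_degraded_scores_below_clean(self, star, degraded_stars, niqe_model):
        clean = dg.niqe_score(star, niqe_model)
        degraded = dg.niqe_score(np.clip(degraded_stars[5.0], 0, 1), niqe_model)
        assert clean > degraded

    def test_degenerate_features_warn(self):
        with pytest.warns(RuntimeWarning):
            dg.train_niqe([np.full((120, 120), 0.5)], 40)

    def test_too_few_blocks_error_names_minimum(self):
        with pytest.raises(ValueError, match="4"):
            dg.train_niqe([np.ones((40, 40))], 40)

    def test_round_trip_reproduces_scores_exactly(self, tmp_path, star, niqe_model):
        path = tmp_path / "model.json"
        save_model(niqe_model, path)
        loaded = load_model(path)
        assert dg.niqe_score(star, loaded) == dg.niqe_score(star, niqe_model)
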