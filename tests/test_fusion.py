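import numpy as np
import pytest

from weedvision import (FeatureSpec, apply_pca, concat_features, fit_pca,
                        select_retention)

# the 24 fusion strategies and their concatenated dimensions
STRATEGY_DIMS = {
    "HOG": 324, "RotLBP": 160, "Gabor": 360, "GLCM": 6, "GGCM": 15, "HU": 8,
    "RotLBP+HOG": 484, "RotLBP+Gabor": 520, "RotLBP+GLCM": 166,
    "GGCM+RotLBP": 175, "RotLBP+HU": 168, "HOG+Gabor": 684,
    "HOG+GLCM": 330, "Gabor+GGCM": 375, "Gabor+HU": 368, "Gabor+GLCM": 366,
    "GGCM+HU": 23, "GGCM+HOG": 339,
    "RotLBP+HOG+Gabor": 844, "GGCM+RotLBP+HOG": 499, "GLCM+RotLBP+HOG": 490,
    "RotLBP+HOG+Gabor+GLCM": 850, "RotLBP+HOG+Gabor+GGCM": 859,
    "RotLBP+HOG+Gabor+HU+GGCM": 867,
}


class TestFeatureSpec:
    @pytest.mark.parametrize("strategy,dim", sorted(STRATEGY_DIMS.items()))
    def test_all_24_strategy_dimensions(self, strategy, dim):
        assert FeatureSpec.parse(strategy).total_dim == dim

    def test_case_insensitive_parsing_preserves_order(self):
        spec = FeatureSpec.parse("ggcm+rotlbp")
        assert spec.descriptors == ("GGCM", "RotLBP")
        assert spec.name == "GGCM+RotLBP"

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec.parse("GGCM+SIFT")

    def test_json_round_trip(self):
        spec = FeatureSpec.parse("GGCM+RotLBP")
        assert FeatureSpec.from_json(spec.to_json()) == spec

    def test_extract_matches_declared_dim(self, rng):
        img = rng.integers(0, 256, (256, 256), dtype=np.uint8)
        spec = FeatureSpec.parse("GGCM+HU")
        assert spec.extract(img).shape == (23,)


class TestConcat:
    def test_lengths_add(self, rng):
        a, b = rng.random(324), rng.random(360)
        out = concat_features([a, b])
        assert out.shape == (684,)
        assert np.array_equal(out[:324], a) and np.array_equal(out[324:], b)

    def test_single_part_identity(self, rng):
        a = rng.random(15)
        assert np.array_equal(concat_features([a]), a)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            concat_features([])


class TestPca:
    def test_full_rank_round_trip_lossless(self, rng):
        X = rng.random((20, 6))
        model = fit_pca(X, 6)
        Z = apply_pca(model, X)
        Xhat = Z @ model.components.T + model.mean
        assert np.allclose(Xhat, X, atol=1e-8)

    def test_recovers_known_eigendirection(self, rng):
        """A cloud elongated along (1,1) has its first component there."""
        t = rng.normal(0, 3, 500)
        noise = rng.normal(0, 0.1, (500, 2))
        X = np.stack([t, t], axis=1) / np.sqrt(2) + noise
        model = fit_pca(X, 1)
        direction = model.components[:, 0]
        target = np.array([1, 1]) / np.sqrt(2)
        angle = np.degrees(np.arccos(np.clip(abs(direction @ target), -1, 1)))
        assert angle < 1.0

    def test_deterministic_sign_convention(self, rng):
        X = rng.random((30, 5))
        a = fit_pca(X, 3)
        b = fit_pca(X.copy(), 3)
        assert np.array_equal(a.components, b.components)
        for j in range(3):
            k = np.argmax(np.abs(a.components[:, j]))
            assert a.components[k, j] > 0

    def test_apply_consistency_and_direct_multiply(self, rng):
        X = rng.random((25, 8))
        model = fit_pca(X, 4)
        Z = apply_pca(model, X)
        x_new = rng.random(8)
        assert np.allclose(apply_pca(model, x_new),
                           (x_new - model.mean) @ model.components, atol=1e-12)
        assert np.allclose(apply_pca(model, X), Z, atol=1e-12)

    def test_zero_variance_column_contributes_nothing(self, rng):
        X = rng.random((30, 4))
        X[:, 2] = 7.0
        model = fit_pca(X, 3)
        assert np.allclose(model.components[2, :], 0, atol=1e-10)

    def test_projected_variance_bounded(self, rng):
        X = rng.random((40, 6))
        model = fit_pca(X, 3)
        Z = apply_pca(model, X)
        assert Z.var(axis=0, ddof=1).sum() <= X.var(axis=0, ddof=1).sum() + 1e-10

    @pytest.mark.parametrize("p", [0, 7, 100])
    def test_out_of_range_retention_rejected(self, p, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.random((8, 6)), p)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_pca(rng.random((10, 5)), 2)
        with pytest.raises(ValueError):
            apply_pca(model, rng.random((3, 4)))


class TestSelectRetention:
    def test_single_candidate_returned(self, rng):
        X = rng.random((40, 5))
        y = np.array([1, -1] * 20)
        best, scores = select_retention(X, y, [3], seed=0)
        assert best == 3 and set(scores) == {3}

    def test_membership(self, rng):
        X = rng.random((40, 6))
        y = np.array([1, -1] * 20)
        best, _ = select_retention(X, y, [2, 4], seed=1)
        assert best in (2, 4)

    def test_signal_concentrated_in_second_component(self, rng):
        """Dominant-variance direction carries no label signal; the label
        lives in the second direction, so p=2 wins over p=1."""
        n = 120
        y = np.repeat([1, -1], n // 2)
        X = np.zeros((n, 6))
        X[:, 0] = rng.normal(0, 5, n)          # loud, uninformative
        X[:, 1] = y * 1.0 + rng.normal(0, 0.1, n)
        X[:, 2:] = rng.normal(0, 0.02, (n, 4))
        for seed in range(3):
            best, scores = select_retention(X, y, [1, 2, 4], seed=seed)
            assert best == 2, scores
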