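"""GLCM, GGCM and Gabor texture descriptors."""

import numpy as np
import pytest

from weedvision.features import (GABOR_WAVELENGTHS, gabor_features, ggcm,
                                 ggcm_stats, glcm, glcm_stats,
                                 gradient_magnitude, offset_for_angle)

from oracles import (ggcm_bruteforce, ggcm_stats_bruteforce, glcm_bruteforce,
                     glcm_stats_bruteforce, sobel_magnitude_bruteforce)


class TestGlcm:
    def test_constant_image_single_entry(self):
        img = np.full((8, 8), 200, dtype=np.uint8)
        P = glcm(img, levels=64)
        q = (200 * 64) // 256
        assert P[q, q] == 1.0 and P.sum() == 1.0

    def test_toy_grid_matches_pair_enumeration(self):
        img = np.array([[0, 0, 255, 255],
                        [0, 0, 255, 255],
                        [0, 255, 255, 0],
                        [255, 255, 0, 0]], dtype=np.uint8)
        for angle in (0, 45, 90, 135):
            off = offset_for_angle(angle)
            P = glcm(img, levels=4, offset=off)
            assert np.allclose(P, glcm_bruteforce(img, 4, off), atol=1e-12)

    def test_normalization(self, rng):
        img = rng.integers(0, 256, (30, 40), dtype=np.uint8)
        assert np.isclose(glcm(img).sum(), 1.0, atol=1e-12)

    def test_single_row_vertical_offset_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((1, 10), dtype=np.uint8), offset=(1, 0))

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((5, 5), dtype=np.uint8), offset=(0, 0))


class TestGlcmStats:
    def test_single_entry_matrix(self):
        P = np.zeros((16, 16))
        P[3, 3] = 1.0
        energy, contrast, corr, sum_ent, ent, idm = glcm_stats(P)
        assert energy == 1.0 and contrast == 0.0 and ent == 0.0
        assert corr == 0.0  # zero variance guard
        assert idm == 1.0

    def test_uniform_matrix_closed_form(self):
        g = 8
        P = np.full((g, g), 1.0 / g ** 2)
        stats = glcm_stats(P)
        assert np.isclose(stats[0], 1.0 / g ** 2)
        assert np.isclose(stats[4], 2 * np.log(g))

    def test_matches_bruteforce_on_toy_image(self, rng):
        img = rng.integers(0, 256, (6, 6), dtype=np.uint8)
        P = glcm(img, levels=8)
        assert np.allclose(glcm_stats(P), glcm_stats_bruteforce(P),
                           atol=1e-10)


class TestGgcm:
    def test_constant_image_gradient_zero_column(self):
        img = np.full((10, 10), 123, dtype=np.uint8)
        H = ggcm(img, 64, 64)
        assert H[:, 1:].sum() == 0
        assert H.sum() == 100

    def test_gradient_matches_sobel_bruteforce(self, rng):
        img = rng.integers(0, 256, (6, 7)).astype(float)
        assert np.allclose(gradient_magnitude(img),
                           sobel_magnitude_bruteforce(img), atol=1e-10)

    def test_step_edge_matches_bruteforce(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[:, 3:] = 220
        H = ggcm(img, 16, 16)
        assert np.allclose(H, ggcm_bruteforce(img, 16, 16), atol=1e-12)

    def test_normalized_form_sums_to_one(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        H = ggcm(img)
        assert np.isclose((H / H.sum()).sum(), 1.0, atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ggcm(np.zeros((2, 5), dtype=np.uint8))


class TestGgcmStats:
    def test_length_fifteen(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        assert ggcm_stats(ggcm(img)).shape == (15,)

    def test_matches_bruteforce_on_toy_image(self, rng):
        img = rng.integers(0, 256, (6, 6), dtype=np.uint8)
        H = ggcm(img, 8, 8)
        assert np.allclose(ggcm_stats(H), ggcm_stats_bruteforce(H),
                           atol=1e-10)

    def test_constant_image_maximizes_small_gradient_dominance(self, rng):
        """A texture-free image puts all mass at gradient level 0, the
        maximum of the small-gradient dominance statistic over any fixture."""
        flat = ggcm_stats(ggcm(np.full((12, 12), 99, dtype=np.uint8)))[0]
        others = [
            rng.integers(0, 256, (12, 12), dtype=np.uint8) for _ in range(5)
        ]
        for img in others:
            assert ggcm_stats(ggcm(img))[0] <= flat + 1e-12

    def test_finite_on_degenerate_inputs(self):
        img = np.full((5, 5), 50, dtype=np.uint8)
        assert np.all(np.isfinite(ggcm_stats(ggcm(img))))


class TestGabor:
    def test_descriptor_length(self, rng):
        img = rng.integers(0, 256, (256, 256), dtype=np.uint8)
        assert gabor_features(img).shape == (360,)

    def test_constant_image_spatially_homogeneous(self):
        img = np.full((128, 128), 90, dtype=np.uint8)
        v = gabor_features(img).reshape(40, 9)
        for filt in v:
            assert np.allclose(filt, filt[0], rtol=1e-6, atol=1e-9)

    def test_orientation_selectivity_on_tuned_grating(self):
        """A grating at a filter's frequency drives the matching orientation
        harder than the orthogonal one."""
        yy, xx = np.mgrid[0:256, 0:256]
        lam = 8.0
        img = 128 + 100 * np.sin(2 * np.pi * xx / lam)
        v = gabor_features(img.astype(float)).reshape(5, 8, 9)
        scale = GABOR_WAVELENGTHS.index(lam)
        aligned = v[scale, 0].mean()      # theta = 0
        orthogonal = v[scale, 4].mean()   # theta = pi/2
        assert aligned > 10 * orthogonal
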