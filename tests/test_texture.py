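"""GLCM construction, the five co-occurrence descriptors, histogram stats.

The oracle used throughout is an independent brute-force implementation:
explicit python loops over every pixel pair and direct evaluation of the
descriptor formulas.
"""

import numpy as np
import pytest

from specgp.images import GrayscaleImage
from specgp.texture import (
    GLCM_ANGLES,
    GLCM_FEATURE_NAMES,
    GLCMMatrix,
    glcm,
    glcm_feature,
    histogram_feature,
)


def glcm_oracle(values, mask, levels, d, angle):
    """Brute-force pair-counting GLCM (independent of the implementation)."""
    roi = values[mask]
    lo, hi = roi.min(), roi.max()
    if hi == lo:
        q = np.zeros(values.shape, dtype=int)
    else:
        q = np.clip(np.floor((values - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    dr = -int(round(d * np.sin(angle)))
    dc = int(round(d * np.cos(angle)))
    counts = np.zeros((levels, levels))
    h, w = values.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def feature_oracle(p, name):
    """Direct double-loop evaluation of the descriptor formulas."""
    L = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * p[i, j] for i in range(L) for j in range(L))
    var_i = sum(p[i, j] * (i - mu_i) ** 2 for i in range(L) for j in range(L))
    var_j = sum(p[i, j] * (j - mu_j) ** 2 for i in range(L) for j in range(L))
    if name == "homogeneity":
        return sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    if name == "entropy":
        return -sum(
            p[i, j] * np.log2(p[i, j])
            for i in range(L)
            for j in range(L)
            if p[i, j] > 0
        )
    if name == "contrast":
        return sum(p[i, j] * (i - j) ** 2 for i in range(L) for j in range(L))
    if name == "correlation":
        denom = np.sqrt(var_i * var_j)
        if denom == 0:
            return 0.0
        return (
            sum((i - mu_i) * (j - mu_j) * p[i, j] for i in range(L) for j in range(L))
            / denom
        )
    if name == "energy":
        return np.sqrt(sum(p[i, j] ** 2 for i in range(L) for j in range(L)))
    raise ValueError(name)


def checkerboard(n=2):
    vals = np.indices((n * 2, n * 2)).sum(axis=0) % 2
    return GrayscaleImage(vals.astype(float), np.ones((n * 2, n * 2), bool))


class TestGLCM:
    def test_constant_image_single_entry(self):
        img = GrayscaleImage(np.full((4, 4), 3.0), np.ones((4, 4), bool))
        m = glcm(img, 1, 0.0, levels=8)
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal_pairs(self):
        # every horizontal neighbour pair alternates 0/1
        m = glcm(checkerboard(1), 1, 0.0, levels=2)
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)
        assert m.p[0, 0] == m.p[1, 1] == 0.0

    @pytest.mark.parametrize("d", [1, 2, 3, 5])
    @pytest.mark.parametrize("angle", GLCM_ANGLES)
    def test_matches_bruteforce_oracle(self, rng, d, angle):
        vals = rng.random((16, 16))
        mask = rng.random((16, 16)) > 0.2
        img = GrayscaleImage(vals, mask)
        m = glcm(img, d, angle, levels=8)
        oracle = glcm_oracle(vals, mask, 8, d, angle)
        np.testing.assert_allclose(m.p, oracle, atol=1e-15)

    def test_matrix_properties(self, rng):
        img = GrayscaleImage(rng.random((12, 12)), np.ones((12, 12), bool))
        m = glcm(img, 2, np.pi / 4, levels=16)
        assert m.p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(m.p, m.p.T, atol=1e-15)
        assert (m.p >= 0).all()

    def test_opposite_angles_equivalent(self, rng):
        vals = rng.random((10, 10))
        img = GrayscaleImage(vals, np.ones((10, 10), bool))
        for angle in GLCM_ANGLES:
            a = glcm(img, 1, angle, levels=8).p
            b = glcm_oracle(vals, img.roi_mask, 8, 1, angle + np.pi)
            np.testing.assert_allclose(a, b, atol=1e-15)

    def test_affine_rescale_invariance(self, rng):
        vals = rng.random((10, 10))
        img1 = GrayscaleImage(vals, np.ones((10, 10), bool))
        img2 = GrayscaleImage(5.0 * vals + 3.0, np.ones((10, 10), bool))
        np.testing.assert_allclose(
            glcm(img1, 1, 0.0, 8).p, glcm(img2, 1, 0.0, 8).p, atol=1e-15
        )

    def test_empty_roi_raises(self):
        img = GrayscaleImage(np.ones((4, 4)), np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            glcm(img, 1, 0.0)

    def test_bad_distance_raises(self, gray):
        with pytest.raises(ValueError):
            glcm(gray, 7, 0.0)


class TestGLCMFeatures:
    def test_constant_image_features(self):
        img = GrayscaleImage(np.full((5, 5), 2.0), np.ones((5, 5), bool))
        m = glcm(img, 1, 0.0, levels=4)
        assert glcm_feature(m, "contrast") == 0.0
        assert glcm_feature(m, "entropy") == 0.0
        assert glcm_feature(m, "energy") == pytest.approx(1.0)
        assert glcm_feature(m, "homogeneity") == pytest.approx(1.0)
        assert glcm_feature(m, "correlation") == 0.0  # degenerate rule

    def test_checkerboard_hand_values(self):
        # p(0,1) = p(1,0) = 0.5 plugged into the five formulas by hand
        m = glcm(checkerboard(1), 1, 0.0, levels=2)
        assert glcm_feature(m, "contrast") == pytest.approx(1.0)
        assert glcm_feature(m, "entropy") == pytest.approx(1.0)  # one bit
        assert glcm_feature(m, "energy") == pytest.approx(np.sqrt(0.5))
        assert glcm_feature(m, "homogeneity") == pytest.approx(0.5)
        assert glcm_feature(m, "correlation") == pytest.approx(-1.0)

    def test_features_match_oracle_on_random_images(self, rng):
        for _ in range(20):
            img = GrayscaleImage(rng.random((10, 10)), np.ones((10, 10), bool))
            m = glcm(img, int(rng.integers(1, 6)), GLCM_ANGLES[int(rng.integers(4))],
                     levels=6)
            for name in GLCM_FEATURE_NAMES:
                assert glcm_feature(m, name) == pytest.approx(
                    feature_oracle(m.p, name), abs=1e-12
                )

    def test_entropy_bounds(self, rng):
        img = GrayscaleImage(rng.random((12, 12)), np.ones((12, 12), bool))
        levels = 8
        m = glcm(img, 1, 0.0, levels=levels)
        assert 0.0 <= glcm_feature(m, "entropy") <= 2 * np.log2(levels)

    def test_energy_is_sqrt_asm(self, rng):
        img = GrayscaleImage(rng.random((8, 8)), np.ones((8, 8), bool))
        m = glcm(img, 1, 0.0, levels=4)
        assert glcm_feature(m, "energy") ** 2 == pytest.approx((m.p**2).sum())


class TestHistogramFeatures:
    def test_constant_image(self):
        img = GrayscaleImage(np.full((3, 3), 4.2), np.ones((3, 3), bool))
        assert histogram_feature(img, "mean") == pytest.approx(4.2)
        assert histogram_feature(img, "sd") == 0.0
        with pytest.raises(ValueError):
            histogram_feature(img, "skewness")
        with pytest.raises(ValueError):
            histogram_feature(img, "kurtosis")

    def test_symmetric_values_zero_skewness(self):
        img = GrayscaleImage(np.array([[-1.0, 0.0, 1.0]]), np.ones((1, 3), bool))
        assert histogram_feature(img, "skewness") == pytest.approx(0.0)

    def test_moments_match_textbook_formulas(self, rng):
        vals = rng.random((6, 6))
        img = GrayscaleImage(vals, np.ones((6, 6), bool))
        x = vals.ravel()
        n = x.size
        mu = x.mean()
        m2 = ((x - mu) ** 2).mean()
        m3 = ((x - mu) ** 3).mean()
        m4 = ((x - mu) ** 4).mean()
        assert histogram_feature(img, "mean") == pytest.approx(mu)
        assert histogram_feature(img, "sd") == pytest.approx(
            np.sqrt(((x - mu) ** 2).sum() / (n - 1))
        )
        assert histogram_feature(img, "skewness") == pytest.approx(m3 / m2**1.5)
        assert histogram_feature(img, "kurtosis") == pytest.approx(m4 / m2**2 - 3.0)

    def test_raw_kurtosis_flag(self, rng):
        vals = rng.random((5, 5))
        img = GrayscaleImage(vals, np.ones((5, 5), bool))
        excess = histogram_feature(img, "kurtosis")
        raw = histogram_feature(img, "kurtosis", excess_kurtosis=False)
        assert raw == pytest.approx(excess + 3.0)
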