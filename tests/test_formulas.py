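"""Formula registry, first-order statistics, texture matrices and shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from radstruct import texture
from radstruct.formulas import (
    DEFAULT_FORMULA_NAMES,
    FORMULA_CATEGORIES,
    GLCM_FORMULAS,
    GLDM_FORMULAS,
    GLRLM_FORMULAS,
    GLSZM_FORMULAS,
    HISTOGRAM_FORMULAS,
    SHAPE_FORMULAS,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    histogram_features,
    shape_features,
    voi_features,
)
from radstruct.texture import GLCM, OFFSETS_13, compute_glcm, quantize


def test_registry_counts():
    assert len(HISTOGRAM_FORMULAS) == 23
    assert len(GLCM_FORMULAS) == 24
    assert len(GLRLM_FORMULAS) == 16
    assert len(GLSZM_FORMULAS) == 16
    assert len(GLDM_FORMULAS) == 14
    assert len(DEFAULT_FORMULA_NAMES) == 93
    assert len(set(DEFAULT_FORMULA_NAMES)) == 93
    assert set(FORMULA_CATEGORIES) == set(DEFAULT_FORMULA_NAMES)
    assert len(SHAPE_FORMULAS) == 12


class TestHistogram:
    def test_symmetric_sample_has_zero_skewness(self):
        feats = histogram_features(np.array([1.0, 2.0, 3.0]))
        assert feats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_percentile_matches_sorting_oracle(self):
        values = np.arange(101.0)
        feats = histogram_features(values)
        # linear-interpolation convention on 0..100
        assert feats["p90"] == pytest.approx(90.0)
        rng = np.random.default_rng(0)
        sample = rng.normal(size=57)
        feats = histogram_features(sample)
        s = np.sort(sample)
        for p, name in ((5, "p5"), (25, "p25"), (90, "p90")):
            pos = (len(s) - 1) * p / 100
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expected = s[lo] + (pos - lo) * (s[hi] - s[lo])
            assert feats[name] == pytest.approx(expected)

    def test_normal_sample_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(123)
        sample = rng.standard_normal(100_000)
        feats = histogram_features(sample)
        se = np.sqrt(24 / sample.size)
        assert abs(feats["kurtosis"]) < 3 * se

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 1000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        sample = rng.normal(size=40)
        perm = rng.permutation(sample)
        a, b = histogram_features(sample), histogram_features(perm)
        for name in HISTOGRAM_FORMULAS:
            assert a[name] == pytest.approx(b[name], rel=1e-12, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(np.array([]))

    def test_constant_sample_imputes_moments(self):
        feats = histogram_features(np.full(10, 3.0))
        assert feats["skewness"] == 0.0
        assert feats["kurtosis"] == 0.0
        assert feats["variance"] == 0.0


class TestGLCM:
    def test_constant_voi_all_mass_on_diagonal(self):
        vol = np.full((4, 4, 4), 2.0)
        g = compute_glcm(vol, np.ones(vol.shape, bool), levels=8)
        assert g.matrix[0, 0] == pytest.approx(1.0)

    def test_checkerboard_zero_diagonal(self):
        # 2x2 checkerboard slice, offset along x only
        vol = np.array([[[0.0, 1.0], [1.0, 0.0]]])
        g = compute_glcm(vol, np.ones(vol.shape, bool), levels=2, offsets=[(0, 0, 1)])
        assert np.trace(g.matrix) == 0.0
        np.testing.assert_allclose(g.matrix, [[0.0, 0.5], [0.5, 0.0]])

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(9)
        vol = rng.random((5, 5, 5))
        mask = rng.random(vol.shape) > 0.3
        g = compute_glcm(vol, mask, levels=4)
        expected = oracles.glcm_pairs_bruteforce(vol, mask, 4, OFFSETS_13)
        np.testing.assert_allclose(g.matrix, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 500))
    def test_normalized_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.random((4, 4, 4))
        g = compute_glcm(vol, np.ones(vol.shape, bool), levels=5)
        assert g.matrix.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(g.matrix, g.matrix.T, atol=1e-15)

    def test_too_few_voxels_rejected(self):
        vol = np.zeros((3, 3, 3))
        mask = np.zeros(vol.shape, bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            compute_glcm(vol, mask, levels=4)


class TestGLCMFormulas:
    def test_constant_voi_contrast_zero(self):
        vol = np.full((3, 3, 3), 1.0)
        g = compute_glcm(vol, np.ones(vol.shape, bool), levels=4)
        assert glcm_features(g)["glcm_contrast"] == 0.0

    def test_symmetric_marginal_zero_cluster_shade(self):
        # doubly symmetric matrix: p and its anti-diagonal flip coincide
        p = np.array([[0.2, 0.1], [0.1, 0.2]])
        g = GLCM(matrix=p / p.sum(), levels=2, offsets=((0, 0, 1),))
        assert glcm_features(g)["glcm_cluster_shade"] == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 500))
    def test_all_formulas_match_literal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((4, 4))
        m = m + m.T
        g = GLCM(matrix=m / m.sum(), levels=4, offsets=((0, 0, 1),))
        ours = glcm_features(g)
        expected = oracles.glcm_features_bruteforce(g.matrix)
        for name in GLCM_FORMULAS:
            assert ours[name] == pytest.approx(expected[name], abs=1e-10), name


class TestRunZoneDependence:
    @pytest.fixture()
    def small_voi(self):
        rng = np.random.default_rng(21)
        vol = rng.random((5, 5, 5))
        mask = rng.random(vol.shape) > 0.25
        q = quantize(vol, 4, mask=mask)
        return q, mask

    def test_glrlm_matches_line_scanning_oracle(self, small_voi):
        q, mask = small_voi
        ours = texture.glrlm_matrix(q, mask, 4)
        expected = oracles.glrlm_bruteforce(q, mask, 4, OFFSETS_13)
        np.testing.assert_allclose(ours[:, : expected.shape[1]], expected)
        assert ours[:, expected.shape[1]:].sum() == 0

    def test_glrlm_hand_example(self):
        # one line: levels 0 0 1 1 1 2 -> runs (0,len2) (1,len3) (2,len1)
        q = np.array([[[0, 0, 1, 1, 1, 2]]])
        mask = np.ones(q.shape, bool)
        m = texture.glrlm_matrix(q, mask, 3, directions=[(0, 0, 1)])
        assert m[0, 1] == 1 and m[1, 2] == 1 and m[2, 0] == 1
        assert m.sum() == 3

    def test_glszm_matches_flood_fill_oracle(self, small_voi):
        q, mask = small_voi
        ours = texture.glszm_matrix(q, mask, 4)
        expected = oracles.glszm_bruteforce(q, mask, 4)
        np.testing.assert_allclose(ours, expected)

    def test_glszm_accounting(self, small_voi):
        q, mask = small_voi
        m = texture.glszm_matrix(q, mask, 4)
        sizes = np.arange(1, m.shape[1] + 1)
        assert (m * sizes).sum() == mask.sum()

    def test_gldm_matches_neighbour_loop_oracle(self, small_voi):
        q, mask = small_voi
        ours = texture.gldm_matrix(q, mask, 4)
        expected = oracles.gldm_bruteforce(q, mask, 4)
        np.testing.assert_allclose(ours, expected)

    def test_matrix_feature_values_finite_and_scaled(self, small_voi):
        q, mask = small_voi
        n = int(mask.sum())
        for fn, matrix in (
            (glrlm_features, texture.glrlm_matrix(q, mask, 4)),
            (glszm_features, texture.glszm_matrix(q, mask, 4)),
            (gldm_features, texture.gldm_matrix(q, mask, 4)),
        ):
            feats = fn(matrix, n)
            assert all(np.isfinite(v) for v in feats.values())


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert feats["volume"] == pytest.approx(1.0)

    def test_ball_volume_near_analytic(self):
        r = 10
        ax = np.arange(-14, 15)
        Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = Z**2 + Y**2 + X**2 <= r**2
        feats = shape_features(ball)
        assert feats["volume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)

    def test_ball_rounder_than_cube(self):
        ax = np.arange(-12, 13)
        Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = Z**2 + Y**2 + X**2 <= 10**2
        cube = np.zeros_like(ball)
        cube[4:21, 4:21, 4:21] = True  # similar volume
        assert shape_features(ball)["sphericity"] > shape_features(cube)["sphericity"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((3, 3, 3), bool))


class TestVoiDispatcher:
    def test_degenerate_voi_imputes_zero(self):
        vol = np.full((3, 3, 3), 1.0)
        feats = voi_features(vol, np.ones(vol.shape, bool))
        assert set(feats) == set(DEFAULT_FORMULA_NAMES)
        assert all(v == 0.0 for v in feats.values())

    def test_unknown_formula_rejected(self):
        vol = np.random.default_rng(0).random((3, 3, 3))
        with pytest.raises(KeyError):
            voi_features(vol, np.ones(vol.shape, bool), ["fractal_dimension"])

    def test_full_formula_set_finite(self):
        rng = np.random.default_rng(2)
        vol = rng.random((6, 6, 6))
        mask = rng.random(vol.shape) > 0.2
        feats = voi_features(vol, mask)
        assert len(feats) == 93
        assert all(np.isfinite(v) for v in feats.values())
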