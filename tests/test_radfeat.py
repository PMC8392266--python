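"""Radiomic features: registry counts, worked examples, oracle checks."""

import numpy as np
import pytest

from gkradiomics.image import ImageVolume
from gkradiomics.radfeat import (
    DIRECTIONS_3D,
    GEOMETRY_FEATURES,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    HISTOGRAM_FEATURES,
    LBP_FEATURES,
    WAVELET_TAGS,
    build_feature_registry,
    discretize_roi,
    extract_all,
    geometry_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    histogram_features,
    lbp_features,
    registry_names,
    wavelet_decompose_3d,
)
from gkradiomics.radfeat.texture import glcm_features_from_matrix, glrlm_features_from_matrix
from gkradiomics.radfeat.wavelet import analysis_filters

import oracles


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing)


# ---------------------------------------------------------------------- #
# registry
# ---------------------------------------------------------------------- #
class TestRegistry:
    def test_total_and_per_family_counts(self):
        entries = build_feature_registry()
        assert len(entries) == 1763
        for contrast in ("T1w", "T1c", "T2w"):
            per = [e for e in entries if e[0] == contrast]
            assert len(per) == 585
            sets = {e[1] for e in per}
            assert len(sets) == 9  # original + 8 subbands
        geometry = [e for e in entries if e[2] == "geometry"]
        assert len(geometry) == 8
        assert len(HISTOGRAM_FEATURES) == 16
        assert len(GLCM_FEATURES) + len(GLRLM_FEATURES) + len(LBP_FEATURES) == 49

    def test_names_unique_and_ordered(self):
        names = registry_names()
        assert len(names) == len(set(names)) == 1763


# ---------------------------------------------------------------------- #
# wavelets
# ---------------------------------------------------------------------- #
class TestWavelet:
    def test_constant_input_annihilated_by_any_high_pass(self):
        vol = _vol(np.full((12, 12, 12), 4.2))
        bands = wavelet_decompose_3d(vol)
        assert len(bands) == 8
        for tag, band in bands.items():
            if "H" in tag:
                assert np.abs(band.data).max() <= 1e-10
            else:
                np.testing.assert_allclose(band.data, 4.2, atol=1e-10)

    def test_impulse_matches_separable_convolution_oracle(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        bands = wavelet_decompose_3d(_vol(data))
        lo, hi = analysis_filters()
        for tag in ("LLL", "LHH", "HLH", "HHH"):
            expected = oracles.wavelet_band_bruteforce(data, lo, hi, tag)
            np.testing.assert_allclose(bands[tag].data, expected, atol=1e-12)

    def test_random_volume_matches_oracle_all_bands(self, rng):
        data = rng.standard_normal((7, 6, 8))
        bands = wavelet_decompose_3d(_vol(data))
        lo, hi = analysis_filters()
        assert set(bands) == set(WAVELET_TAGS)
        for tag, band in bands.items():
            expected = oracles.wavelet_band_bruteforce(data, lo, hi, tag)
            np.testing.assert_allclose(band.data, expected, atol=1e-10)

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError):
            wavelet_decompose_3d(_vol(np.zeros((4, 9, 9))))


# ---------------------------------------------------------------------- #
# discretization
# ---------------------------------------------------------------------- #
class TestDiscretize:
    def test_bin_edges_right_closed_top(self):
        data = np.array([[[0.0, 0.5, 1.0]]])
        mask = np.ones_like(data, dtype=bool)
        roi = discretize_roi(data, mask, 2)
        assert roi.levels[mask].tolist() == [1, 2, 2]

    @pytest.mark.parametrize("n_levels", [1, 4, 32])
    def test_constant_roi_all_level_one(self, n_levels):
        data = np.full((3, 3, 3), 7.0)
        roi = discretize_roi(data, np.ones_like(data, bool), n_levels)
        assert set(roi.levels[roi.mask]) == {1}

    def test_levels_within_range_and_all_labeled(self, rng):
        data = rng.standard_normal((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.4
        roi = discretize_roi(data, mask, 8)
        inside = roi.levels[mask]
        assert inside.min() >= 1 and inside.max() <= 8
        assert (roi.levels[~mask] == 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            discretize_roi(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))


# ---------------------------------------------------------------------- #
# GLCM
# ---------------------------------------------------------------------- #
class TestGLCM:
    def test_constant_roi_degenerate_conventions(self):
        roi = discretize_roi(np.full((3, 3, 3), 1.0), np.ones((3, 3, 3), bool), 32)
        f = glcm_features(roi)
        assert f["contrast"] == 0.0
        assert f["homogeneity1"] == pytest.approx(1.0)
        assert f["imc1"] == 0.0
        assert f["correlation"] == 0.0
        assert f["energy"] == pytest.approx(1.0)

    def test_2x2x1_roi_matches_pair_enumeration_oracle(self):
        data = np.array([[[1.0], [2.0]], [[1.0], [2.0]]])
        mask = np.ones_like(data, bool)
        roi = discretize_roi(data, mask, 2)
        for d in DIRECTIONS_3D:
            p_impl = glcm_matrix(roi, d)
            p_oracle = oracles.glcm_matrix_bruteforce(roi.levels, d, 2)
            np.testing.assert_allclose(p_impl, p_oracle, atol=1e-12)
            if p_impl.sum() > 0:
                impl = glcm_features_from_matrix(p_impl)
                orc = oracles.glcm_features_bruteforce(p_oracle)
                for name in GLCM_FEATURES:
                    assert impl[name] == pytest.approx(orc[name], abs=1e-9), name

    def test_checkerboard_face_direction_correlation_is_minus_one(self):
        g = np.indices((4, 4, 4)).sum(axis=0)
        data = (g % 2).astype(float)
        roi = discretize_roi(data, np.ones_like(data, bool), 2)
        for d in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            p = glcm_matrix(roi, d)
            f = glcm_features_from_matrix(p)
            orc = oracles.glcm_features_bruteforce(oracles.glcm_matrix_bruteforce(roi.levels, d, 2))
            assert f["correlation"] == pytest.approx(-1.0, abs=1e-12)
            assert orc["correlation"] == pytest.approx(-1.0, abs=1e-12)

    def test_direction_average_invariant_to_axis_permutation(self, rng):
        data = rng.standard_normal((5, 6, 7))
        mask = rng.random((5, 6, 7)) > 0.3
        roi = discretize_roi(data, mask, 6)
        f0 = glcm_features(roi)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            roi_p = discretize_roi(np.transpose(data, perm), np.transpose(mask, perm), 6)
            fp = glcm_features(roi_p)
            for name in GLCM_FEATURES:
                assert fp[name] == pytest.approx(f0[name], abs=1e-6), name


# ---------------------------------------------------------------------- #
# GLRLM
# ---------------------------------------------------------------------- #
class TestGLRLM:
    def test_single_line_single_run_hand_values(self):
        data = np.ones((1, 1, 4))
        roi = discretize_roi(data, np.ones_like(data, bool), 1)
        r = glrlm_matrix(roi, (0, 0, 1))
        f = glrlm_features_from_matrix(r, roi.n_voxels)
        assert f["sre"] == pytest.approx(1.0 / 16.0)
        assert f["lre"] == pytest.approx(16.0)
        assert f["rp"] == pytest.approx(1.0 / 4.0)

    def test_alternating_line_all_runs_length_one(self):
        data = np.array([[[1.0, 2.0, 1.0, 2.0, 1.0]]])
        roi = discretize_roi(data, np.ones_like(data, bool), 2)
        f = glrlm_features_from_matrix(glrlm_matrix(roi, (0, 0, 1)), roi.n_voxels)
        assert f["sre"] == pytest.approx(1.0)
        assert f["rp"] == pytest.approx(1.0)

    def test_direction_matrices_match_line_walking_oracle(self, rng):
        data = rng.standard_normal((5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.3
        roi = discretize_roi(data, mask, 4)
        for d in DIRECTIONS_3D:
            impl = glrlm_matrix(roi, d)
            orc = oracles.glrlm_matrix_bruteforce(roi.levels, d, 4)
            # pad to common width before comparing
            w = max(impl.shape[1], orc.shape[1])
            impl = np.pad(impl, [(0, 0), (0, w - impl.shape[1])])
            orc = np.pad(orc, [(0, 0), (0, w - orc.shape[1])])
            np.testing.assert_allclose(impl, orc, atol=0)

    def test_direction_average_equals_mean_of_oracle_features(self, rng):
        data = rng.standard_normal((4, 5, 4))
        mask = rng.random((4, 5, 4)) > 0.25
        roi = discretize_roi(data, mask, 3)
        impl = glrlm_features(roi)
        per_dir = [
            oracles.glrlm_features_bruteforce(
                oracles.glrlm_matrix_bruteforce(roi.levels, d, 3), roi.n_voxels
            )
            for d in DIRECTIONS_3D
        ]
        for name in GLRLM_FEATURES:
            expected = np.mean([f[name] for f in per_dir])
            assert impl[name] == pytest.approx(expected, abs=1e-9), name


# ---------------------------------------------------------------------- #
# LBP
# ---------------------------------------------------------------------- #
class TestLBP:
    def test_constant_slice_one_hot_at_all_bits_set(self):
        data = np.full((6, 6, 1), 2.0)
        f = lbp_features(data, np.ones_like(data, bool))
        hist = [f[n] for n in LBP_FEATURES]
        assert hist[8] == pytest.approx(1.0)
        assert sum(hist) == pytest.approx(1.0)

    def test_center_below_neighbours_uniform_code(self):
        data = np.ones((3, 3, 1))
        data[1, 1, 0] = 0.0
        mask = np.zeros((3, 3, 1), bool)
        mask[1, 1, 0] = True
        f = lbp_features(data, mask)
        # all 8 thresholded neighbours are >= center: uniform code with 8 bits
        assert f["lbp_8"] == pytest.approx(1.0)

    def test_histogram_sums_to_one_and_matches_oracle(self, rng):
        data = rng.standard_normal((6, 6, 3))
        mask = rng.random((6, 6, 3)) > 0.3
        mask[3, 3, 1] = True
        f = lbp_features(data, mask)
        hist = np.array([f[n] for n in LBP_FEATURES])
        assert hist.sum() == pytest.approx(1.0)
        expected = oracles.lbp_histogram_bruteforce(data, mask)
        np.testing.assert_allclose(hist, expected, atol=1e-9)


# ---------------------------------------------------------------------- #
# histogram
# ---------------------------------------------------------------------- #
class TestHistogram:
    def test_four_value_roi_direct_arithmetic(self):
        data = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        f = histogram_features(data, np.ones_like(data, bool))
        assert f["minimum"] == 1 and f["maximum"] == 4
        assert f["mean"] == pytest.approx(2.5)
        assert f["range"] == pytest.approx(3.0)

    def test_uniform_discretized_distribution_entropy_log2_b(self):
        b = 8
        data = (np.arange(64, dtype=float) % b).reshape(4, 4, 4)
        f = histogram_features(data, np.ones((4, 4, 4), bool), n_levels=b)
        assert f["entropy"] == pytest.approx(np.log2(b))
        assert f["uniformity"] == pytest.approx(1.0 / b)

    def test_constant_roi_degenerate_moments_zero(self):
        f = histogram_features(np.full((3, 3, 3), 2.0), np.ones((3, 3, 3), bool))
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0

    def test_matches_direct_statistics_oracle(self, rng):
        data = rng.normal(1, 3, (6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.4
        impl = histogram_features(data, mask)
        orc = oracles.histogram_features_bruteforce(data, mask)
        for name in HISTOGRAM_FEATURES:
            assert impl[name] == pytest.approx(orc[name], abs=1e-9), name


# ---------------------------------------------------------------------- #
# geometry
# ---------------------------------------------------------------------- #
class TestGeometry:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = geometry_features(mask, (1.0, 1.0, 1.0))
        assert f["volume_mm3"] == 1.0
        assert f["surface_area_mm2"] == 6.0
        assert f["max_diameter_mm"] == 0.0

    def test_2x2x2_cube_face_counting_oracle(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        f = geometry_features(mask, (1.0, 1.0, 1.0))
        assert f["volume_mm3"] == 8.0
        assert f["surface_area_mm2"] == 24.0
        assert f["max_diameter_mm"] == pytest.approx(np.sqrt(3.0))

    def test_ball_vs_cube_sphericity_under_face_counting(self):
        g = np.indices((15, 15, 15))
        ball = (((g - 7) ** 2).sum(axis=0)) <= 36
        cube = np.zeros((15, 15, 15), bool)
        side = int(round(ball.sum() ** (1 / 3)))
        cube[:side, :side, :side] = True
        fb = geometry_features(ball, (1, 1, 1))
        fc = geometry_features(cube, (1, 1, 1))
        orc_b = oracles.geometry_features_bruteforce(ball, (1, 1, 1))
        orc_c = oracles.geometry_features_bruteforce(cube, (1, 1, 1))
        assert fb["sphericity"] == pytest.approx(orc_b["sphericity"], abs=1e-9)
        assert fc["sphericity"] == pytest.approx(orc_c["sphericity"], abs=1e-9)
        # exposed-face counting inflates a digital ball's area by ~1.5x
        # (staircase effect), so the axis-aligned cube scores higher; both
        # stay below the ideal sphere's 1.0
        assert fc["sphericity"] > fb["sphericity"]
        assert fb["sphericity"] < 1.0 and fc["sphericity"] < 1.0
        # the staircase ratio itself: ball area / smooth sphere area ~ 1.5
        r = (3 * fb["volume_mm3"] / (4 * np.pi)) ** (1 / 3)
        assert fb["surface_area_mm2"] / (4 * np.pi * r**2) == pytest.approx(1.5, rel=0.1)

    def test_matches_bruteforce_oracle_anisotropic(self, rng):
        mask = rng.random((5, 6, 4)) > 0.5
        mask[2, 3, 2] = True
        impl = geometry_features(mask, (1.0, 0.8, 2.5))
        orc = oracles.geometry_features_bruteforce(mask, (1.0, 0.8, 2.5))
        for name in GEOMETRY_FEATURES:
            assert impl[name] == pytest.approx(orc[name], abs=1e-9), name


# ---------------------------------------------------------------------- #
# full extraction
# ---------------------------------------------------------------------- #
class TestExtractAll:
    @pytest.fixture(scope="class")
    def lesion_fixture(self):
        rng = np.random.default_rng(5)
        shape = (20, 20, 20)
        g = np.indices(shape)
        mask = (((g - 10) ** 2).sum(axis=0)) <= 16
        vols = {
            c: ImageVolume(data=rng.standard_normal(shape), spacing=(1, 1, 1), contrast=c)
            for c in ("T1w", "T1c", "T2w")
        }
        return vols, mask

    def test_vector_length_and_per_contrast_counts(self, lesion_fixture):
        vols, mask = lesion_fixture
        fv = extract_all(vols["T1w"], vols["T1c"], vols["T2w"], mask)
        assert len(fv) == 1763
        assert np.all(np.isfinite(fv.to_numpy()))
        for c in ("T1w", "T1c", "T2w"):
            assert sum(n.startswith(f"{c}.") for n in fv.index) == 585
        assert sum(n.startswith("shape.") for n in fv.index) == 8

    def test_rotated_lesion_preserves_direction_averaged_texture(self, lesion_fixture):
        vols, mask = lesion_fixture
        fv0 = extract_all(vols["T1w"], vols["T1c"], vols["T2w"], mask)
        rot = lambda a: np.rot90(a, k=1, axes=(0, 1)).copy()
        vols_r = {
            c: ImageVolume(data=rot(v.data), spacing=(1, 1, 1), contrast=c)
            for c, v in vols.items()
        }
        fv1 = extract_all(vols_r["T1w"], vols_r["T1c"], vols_r["T2w"], rot(mask))
        # in-plane 90-degree rotation maps the 13 directions onto each other
        # but permutes wavelet axis tags; compare the unfiltered image set
        for name in fv0.index:
            contrast, tag, family, feat = name.split(".", 3)
            if tag == "none" and family in ("glcm", "glrlm"):
                assert fv1[name] == pytest.approx(fv0[name], abs=1e-6), name

    def test_constant_lesion_yields_finite_vector(self):
        shape = (16, 16, 16)
        g = np.indices(shape)
        mask = (((g - 8) ** 2).sum(axis=0)) <= 9
        vols = {
            c: ImageVolume(data=np.full(shape, 1.0), spacing=(1, 1, 1), contrast=c)
            for c in ("T1w", "T1c", "T2w")
        }
        fv = extract_all(vols["T1w"], vols["T1c"], vols["T2w"], mask)
        assert np.all(np.isfinite(fv.to_numpy()))

    def test_grid_mismatch_rejected(self, lesion_fixture):
        vols, mask = lesion_fixture
        bad = ImageVolume(data=np.zeros((10, 10, 10)), spacing=(1, 1, 1), contrast="T2w")
        with pytest.raises(ValueError):
            extract_all(vols["T1w"], vols["T1c"], bad, mask)
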