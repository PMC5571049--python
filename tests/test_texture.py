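"""Texture extraction: discretization, whole-VOI families, patch matrices,
lesion aggregation and the documented invariances."""

import numpy as np
import pytest

from spntex import (
    EmptyVOIError,
    ImageVolume,
    VOIMask,
    cohort_feature_matrix,
    discretize,
    extract_patches,
    first_order_features,
    gaussian_random_field,
    glcm_features,
    glrlm_features,
    histogram_features,
    lesion_features,
    ngldm_features,
    ngtdm_features,
)
from spntex.texture import FEATURE_NAMES, MATRIX_NAMES, Patch
from spntex.texture.patches import patch_matrix_features

from conftest import cube_volume, full_mask
from oracles import (
    glcm_oracle,
    glrlm_oracle,
    ngldm_oracle,
    ngtdm_oracle,
    random_patch,
)


def _const_patch(value=3, n_bins=8):
    bins = np.full((5, 5, 5), value, dtype=np.int64)
    return Patch(bins=bins, valid=np.ones((5, 5, 5), dtype=bool), center_index=(2, 2, 2))


def _checkerboard_patch():
    z, y, x = np.indices((5, 5, 5))
    bins = 1 + (z + y + x) % 2
    return Patch(bins=bins.astype(np.int64), valid=np.ones((5, 5, 5), dtype=bool),
                 center_index=(2, 2, 2))


class TestDiscretize:
    def test_ramp_spans_full_bin_range(self):
        arr = np.linspace(0, 1, 64).reshape(4, 4, 4)
        binned = discretize(cube_volume(arr), full_mask((4, 4, 4)), n_bins=256)
        assert binned.bins[0, 0, 0] == 1
        assert binned.bins[-1, -1, -1] == 256

    def test_constant_voi_all_bin_one(self):
        binned = discretize(cube_volume(np.full((3, 3, 3), 2.0)), full_mask((3, 3, 3)))
        assert (binned.bins == 1).all()

    def test_at_most_n_bins_distinct(self, rng):
        arr = rng.uniform(0, 10, (6, 6, 6))
        binned = discretize(cube_volume(arr), full_mask((6, 6, 6)), n_bins=16)
        assert len(np.unique(binned.bins)) <= 16
        assert binned.bins.min() >= 1

    def test_internal_edge_goes_to_higher_bin(self):
        # range [0, 4] with 4 bins: edges at 1, 2, 3; value 2.0 -> bin 3
        arr = np.zeros((1, 1, 8))
        arr[0, 0] = [0, 4, 2.0, 1.0, 3.0, 0.5, 2.5, 3.999]
        binned = discretize(cube_volume(arr), full_mask((1, 1, 8)), n_bins=4)
        assert binned.bins[0, 0, 1] == 4   # max -> top bin
        assert binned.bins[0, 0, 2] == 3   # edge value goes up
        assert binned.bins[0, 0, 3] == 2

    def test_empty_mask_raises(self):
        empty = VOIMask(np.zeros((3, 3, 3), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(EmptyVOIError):
            discretize(cube_volume(np.ones((3, 3, 3))), empty)


class TestWholeVOIFamilies:
    def test_constant_voi_histogram(self):
        shape = (10, 10, 10)  # 1000 voxels at (2.5, 2, 2) mm = 10 mL
        vol = ImageVolume(np.full(shape, 4.0), (2.5, 2.0, 2.0), "PET", "early", "SUV")
        mask = VOIMask(np.ones(shape, dtype=np.uint8), (2.5, 2.0, 2.0))
        f = histogram_features(vol, mask)
        assert f["HistMean"] == pytest.approx(4.0)
        assert f["Volume"] == pytest.approx(10.0)
        assert f["TotalLesionGlycolysis"] == pytest.approx(40.0)
        assert f["StandardDeviation"] == 0.0
        assert f["HistEntropy"] == 0.0

    def test_symmetric_two_point_has_zero_skewness(self):
        arr = np.array([2.0, 6.0, 2.0, 6.0] * 2).reshape(2, 2, 2)
        f = histogram_features(cube_volume(arr), full_mask((2, 2, 2)))
        assert f["HistSkewness"] == pytest.approx(0.0, abs=1e-12)

    def test_order_statistics(self, rng):
        arr = rng.uniform(0, 9, (5, 5, 5))
        f = histogram_features(cube_volume(arr), full_mask((5, 5, 5)))
        assert f["Max"] >= f["HistMean"] >= f["Min"]

    def test_first_order_hand_example(self):
        arr = np.array([2.0, 2.0, 4.0, 4.0]).reshape(1, 1, 4)
        f = first_order_features(cube_volume(arr), full_mask((1, 1, 4)))
        assert f["Mean"] == pytest.approx(3.0)
        assert f["Variance"] == pytest.approx(1.0)
        assert f["CoefficientOfVariation"] == pytest.approx(1.0 / 3.0)

    def test_first_order_scaling_laws(self, rng):
        arr = rng.uniform(1, 5, (4, 4, 4))
        mask = full_mask((4, 4, 4))
        f1 = first_order_features(cube_volume(arr), mask)
        f2 = first_order_features(cube_volume(2 * arr), mask)
        assert f2["Mean"] == pytest.approx(2 * f1["Mean"])
        assert f2["Median"] == pytest.approx(2 * f1["Median"])
        assert f2["CoefficientOfVariation"] == pytest.approx(f1["CoefficientOfVariation"])
        assert f2["Skewness"] == pytest.approx(f1["Skewness"])

    def test_constant_voi_first_order_degenerates_to_zero(self):
        f = first_order_features(cube_volume(np.full((3, 3, 3), 5.0)), full_mask((3, 3, 3)))
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Kurtosis"] == 0.0


class TestExtractPatches:
    def test_one_patch_per_voi_voxel(self, rng):
        shape = (8, 8, 8)
        mask_arr = (rng.random(shape) < 0.3).astype(np.uint8)
        mask_arr[4, 4, 4] = 1
        mask = VOIMask(mask_arr, (1, 1, 1))
        binned = discretize(cube_volume(rng.uniform(0, 5, shape)), mask)
        patches = list(extract_patches(binned, mask))
        assert len(patches) == mask.n_voxels

    def test_corner_center_has_27_valid(self):
        shape = (8, 8, 8)
        mask_arr = np.zeros(shape, dtype=np.uint8)
        mask_arr[0, 0, 0] = 1
        mask = VOIMask(mask_arr, (1, 1, 1))
        binned = discretize(cube_volume(np.random.default_rng(0).uniform(1, 2, shape)), mask)
        (patch,) = extract_patches(binned, mask)
        assert patch.valid.sum() == 27

    def test_interior_center_fully_valid(self):
        shape = (9, 9, 9)
        mask_arr = np.zeros(shape, dtype=np.uint8)
        mask_arr[4, 4, 4] = 1
        mask = VOIMask(mask_arr, (1, 1, 1))
        binned = discretize(cube_volume(np.ones(shape)), mask)
        (patch,) = extract_patches(binned, mask)
        assert patch.valid.sum() == 125


class TestPatchFamilies:
    def test_constant_patch_glcm(self):
        f = glcm_features(_const_patch())
        assert f["ContrastGLCM"] == 0.0
        assert f["EntropyGLCM"] == 0.0
        assert f["MaximumProbability"] == 1.0

    def test_checkerboard_glcm_contrast(self):
        # Distance-1 axis pairs always differ by one bin (contrast 1); the
        # six in-plane diagonals connect equal bins (contrast 0): mean 0.5.
        f = glcm_features(_checkerboard_patch())
        assert f["ContrastGLCM"] == pytest.approx(0.5)

    def test_constant_patch_glrlm_run_percentage(self):
        # Axis directions: 25 runs of length 5 (RP 0.2).  Each plane-diagonal
        # direction has 45 maximal lines (RP 45/125).  Mean over the 12
        # combinations (6 axis-weighted, 6 diagonal): (6*.2 + 6*.36)/12.
        f = glrlm_features(_const_patch())
        assert f["RunPercentage"] == pytest.approx((6 * 0.2 + 6 * 0.36) / 12)

    def test_alternating_bins_short_runs(self):
        z, y, x = np.indices((5, 5, 5))
        bins = (1 + x % 2).astype(np.int64)  # alternates along the column axis
        patch = Patch(bins=bins, valid=np.ones((5, 5, 5), bool), center_index=(2, 2, 2))
        f = glrlm_features(patch)
        oracle = glrlm_oracle(bins, patch.valid)
        assert f["SmallRunEmphasis"] == pytest.approx(oracle["SmallRunEmphasis"], rel=1e-12)

    def test_all_distinct_bins_ngldm(self):
        bins = (np.arange(125, dtype=np.int64) + 1).reshape(5, 5, 5)
        patch = Patch(bins=bins, valid=np.ones((5, 5, 5), bool), center_index=(2, 2, 2))
        f = ngldm_features(patch)
        assert f["SmallNumberEmphasis"] == pytest.approx(1.0)

    def test_constant_patch_ngldm_large_number_emphasis(self):
        f = ngldm_features(_const_patch())
        # 27 interior voxels have the maximal dependence 26
        assert f["LargeNumberEmphasis"] > 300

    def test_constant_patch_ngtdm(self):
        f = ngtdm_features(_const_patch())
        assert f["Busyness"] == 0.0
        assert f["Coarseness"] == pytest.approx(1e6)

    def test_checkerboard_ngtdm_contrast_exceeds_constant(self):
        fc = ngtdm_features(_checkerboard_patch())
        f0 = ngtdm_features(_const_patch())
        assert fc["ContrastNGL"] > f0["ContrastNGL"]

    def test_single_valid_voxel_degenerate_policy(self):
        valid = np.zeros((5, 5, 5), dtype=bool)
        valid[2, 2, 2] = True
        patch = Patch(bins=np.full((5, 5, 5), 3, np.int64), valid=valid,
                      center_index=(2, 2, 2))
        f = patch_matrix_features(patch)
        assert f["ContrastGLCM"] == 0.0
        assert f["SmallRunEmphasis"] == 1.0
        assert f["Coarseness"] == pytest.approx(1e6)
        assert all(np.isfinite(v) for v in f.values())

    def test_random_patches_match_oracles(self, rng):
        for _ in range(8):
            n_bins = int(rng.integers(2, 17))
            bins, valid = random_patch(rng, n_bins, p_invalid=0.5)
            patch = Patch(bins=bins, valid=valid, center_index=(2, 2, 2))
            impl = patch_matrix_features(patch, n_bins=n_bins)
            oracle = {}
            for fn in (glcm_oracle, glrlm_oracle, ngldm_oracle, ngtdm_oracle):
                oracle.update(fn(bins, valid))
            for name, expected in oracle.items():
                assert impl[name] == pytest.approx(expected, rel=1e-10, abs=1e-12), name


class TestLesionFeatures:
    def test_59_finite_entries(self, small_study):
        fv = lesion_features(small_study.early_pet, small_study.early_mask)
        assert list(fv.index) == FEATURE_NAMES
        assert np.isfinite(fv.to_numpy()).all()

    def test_axis_permutation_invariance(self, small_study):
        vol, mask = small_study.early_pet, small_study.early_mask
        iso = ImageVolume(vol.voxels, (1, 1, 1), "PET", "early", "SUV")
        iso_mask = VOIMask(mask.voxels.astype(np.uint8), (1, 1, 1))
        f1 = lesion_features(iso, iso_mask, n_bins=32)
        perm = ImageVolume(np.transpose(vol.voxels, (2, 0, 1)), (1, 1, 1), "PET", "early", "SUV")
        perm_mask = VOIMask(np.transpose(mask.voxels, (2, 0, 1)).astype(np.uint8), (1, 1, 1))
        f2 = lesion_features(perm, perm_mask, n_bins=32)
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-9)

    def test_gray_level_shift_invariance(self, small_study):
        vol, mask = small_study.early_pet, small_study.early_mask
        f1 = lesion_features(vol, mask, n_bins=64)
        shifted = ImageVolume(vol.voxels + 100.0, vol.spacing_mm, "PET", "early", "SUV")
        f2 = lesion_features(shifted, mask, n_bins=64)
        np.testing.assert_allclose(
            f2[MATRIX_NAMES].to_numpy(), f1[MATRIX_NAMES].to_numpy(), rtol=1e-9
        )
        assert f2["Max"] == pytest.approx(f1["Max"] + 100.0)

    def test_translation_invariance(self, rng):
        content = rng.uniform(1, 6, (7, 7, 7))
        shape = (20, 20, 20)
        f = []
        # both placements keep the 5x5x5 patches fully inside the image so
        # the lesions see identical (constant-background) surroundings
        for corner in ((3, 3, 3), (11, 11, 10)):
            arr = np.full(shape, 0.2)
            msk = np.zeros(shape, dtype=np.uint8)
            sl = tuple(slice(c, c + 7) for c in corner)
            arr[sl] = content
            msk[sl] = 1
            f.append(lesion_features(cube_volume(arr), VOIMask(msk, (1, 1, 1)), n_bins=32))
        np.testing.assert_allclose(f[0].to_numpy(), f[1].to_numpy(), rtol=1e-12)

    def test_monotone_texture_response(self):
        # Shorter correlation length => busier, less coarse texture.
        shape, spacing = (13, 13, 13), (2.0, 2.0, 2.0)
        zz, yy, xx = np.indices(shape)
        sphere = ((zz - 6) ** 2 + (yy - 6) ** 2 + (xx - 6) ** 2) <= 25
        mask = VOIMask(sphere.astype(np.uint8), spacing)
        busy = {}
        coarse = {}
        for corr in (2.0, 4.0, 8.0):
            b, c = [], []
            for seed in range(5):
                field = gaussian_random_field(shape, corr, spacing, seed)
                vol = ImageVolume(np.clip(5.0 + field, 0.01, None), spacing, "PET", "early", "SUV")
                fv = lesion_features(vol, mask, n_bins=32)
                b.append(fv["Busyness"])
                c.append(fv["Coarseness"])
            busy[corr] = np.mean(b)
            coarse[corr] = np.mean(c)
        assert busy[2.0] > busy[4.0] > busy[8.0]
        assert coarse[2.0] < coarse[4.0] < coarse[8.0]


class TestCohortMatrix:
    def test_matrix_shape_and_columns(self, small_study):
        matrix, labels = cohort_feature_matrix([small_study])
        assert matrix.shape == (1, 177)
        assert "dPET_Busyness" in matrix.columns
        assert matrix.notna().all().all()

    def test_empty_cohort(self):
        matrix, labels = cohort_feature_matrix([])
        assert matrix.shape == (0, 177)
        assert len(labels) == 0
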