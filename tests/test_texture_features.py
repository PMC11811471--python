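import numpy as np
import pytest

from rtfpipe import (
    BinaryMask,
    ExtractionSettings,
    ParametricMap,
    PhantomSpec,
    discretize_roi,
    extract_all,
    feature_manifest,
    generate_map,
    resample_inplane,
)
from rtfpipe.filter_bank import FILTER_LABELS
from rtfpipe.texture_features import (
    FEATURE_CLASS_COUNTS,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    firstorder_features,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

from conftest import random_discretized_roi
from naive import (
    DIRECTIONS,
    naive_firstorder,
    naive_glcm,
    naive_glcm_features,
    naive_gldm,
    naive_gldm_features,
    naive_glrlm,
    naive_glrlm_features,
    naive_glszm,
    naive_glszm_features,
    naive_ngtdm,
    naive_ngtdm_features,
)


class TestResample:
    def test_noop_at_target_spacing(self, small_map):
        pmap, mask = small_map
        out_map, out_mask = resample_inplane(pmap, mask)
        assert np.array_equal(out_map.values, pmap.values)
        assert np.array_equal(out_mask.grid, mask.grid)

    def test_2mm_input_roughly_quadruples_pixel_count(self):
        spec = PhantomSpec(grid_shape=(48, 48), pixel_spacing=(2.0, 2.0),
                           ring_radii=(10.0, 22.0))
        pmap, mask = generate_map(spec, seed=1)
        out_map, out_mask = resample_inplane(pmap, mask)
        assert out_map.pixel_spacing == (1.0, 1.0)
        for axis in (0, 1):
            assert abs(out_map.values.shape[axis] - 2 * pmap.values.shape[axis]) <= 1

    def test_mask_stays_binary_under_nearest_neighbour(self):
        checker = np.indices((10, 10)).sum(axis=0) % 2 == 0
        pmap = ParametricMap(np.random.default_rng(0).random((10, 10)), (2.0, 2.0))
        mask = BinaryMask(checker, (2.0, 2.0))
        _, out_mask = resample_inplane(pmap, mask)
        assert out_mask.grid.dtype == bool


class TestDiscretize:
    def test_floor_rule_on_stated_values(self):
        values = np.array([[0.0, 24.9, 25.0, 50.0]])
        mask = np.ones((1, 4), dtype=bool)
        d = discretize_roi(values, mask, bin_width=25.0)
        assert d.levels.tolist() == [1, 1, 2, 3]
        assert d.n_levels == 3

    def test_constant_roi_is_single_level(self):
        d = discretize_roi(np.full((3, 3), 7.0), np.ones((3, 3), bool), 25.0)
        assert d.n_levels == 1 and set(d.levels) == {1}

    def test_histogram_matches_loop_computation(self, rng):
        values = rng.random((10, 10)) * 100
        mask = np.ones((10, 10), bool)
        d = discretize_roi(values, mask, bin_width=10.0)
        loop_counts = {}
        for v in values.ravel():
            lv = int((v - values.min()) // 10.0) + 1
            loop_counts[lv] = loop_counts.get(lv, 0) + 1
        fast_counts = dict(zip(*np.unique(d.levels, return_counts=True)))
        assert {k: int(v) for k, v in fast_counts.items()} == loop_counts

    def test_nonfinite_values_rejected(self):
        values = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            discretize_roi(values, np.ones((1, 2), bool), 1.0)


class TestMatrixBuilders:
    def test_uniform_2x2_glcm_is_unit_mass(self):
        d = discretize_roi(np.full((2, 2), 5.0), np.ones((2, 2), bool), 25.0)
        for mat in build_glcm(d):
            np.testing.assert_allclose(mat, [[1.0]])

    def test_vertical_stripes_horizontal_offset_off_diagonal(self):
        # two-level vertical stripes: horizontally adjacent pixels always differ
        values = np.tile([0.0, 30.0], (4, 2))
        d = discretize_roi(values, np.ones((4, 4), bool), 25.0)
        horizontal = build_glcm(d)[0]
        assert horizontal[0, 0] == 0 and horizontal[1, 1] == 0
        expected = naive_glcm(d.level_image, d.mask, d.n_levels, (0, 1))
        np.testing.assert_allclose(horizontal, expected)

    def test_glcm_symmetry(self, rng):
        d = random_discretized_roi(rng)
        for mat in build_glcm(d):
            np.testing.assert_allclose(mat, mat.T)

    def test_constant_3x3_runs_and_zones(self):
        d = discretize_roi(np.full((3, 3), 1.0), np.ones((3, 3), bool), 25.0)
        horizontal = build_glrlm(d)[0]
        assert horizontal[0, 2] == 3  # three horizontal runs of length 3
        szm = build_glszm(d)
        assert szm[0, 8] == 1 and szm.sum() == 1  # single 9-pixel zone

    def test_single_pixel_roi_degenerate_cases(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        d = discretize_roi(np.full((3, 3), 4.0), mask, 25.0)
        szm = build_glszm(d)
        assert szm[0, 0] == 1 and szm.sum() == 1
        stats = build_ngtdm(d)
        assert stats["n_valid"] == 0 and stats["s"].sum() == 0

    @pytest.mark.parametrize("builder,naive,per_direction", [
        (build_glrlm, naive_glrlm, True),
        (build_glszm, naive_glszm, False),
    ])
    def test_matrices_match_naive_scans(self, rng, builder, naive, per_direction):
        for _ in range(30):
            d = random_discretized_roi(rng)
            if per_direction:
                got = builder(d)
                for mat, direction in zip(got, DIRECTIONS):
                    expected = naive(d.level_image, d.mask, d.n_levels, direction)
                    np.testing.assert_allclose(mat, expected)
            else:
                np.testing.assert_allclose(
                    builder(d), naive(d.level_image, d.mask, d.n_levels))

    def test_gldm_and_ngtdm_match_naive_loops(self, rng):
        for _ in range(30):
            d = random_discretized_roi(rng)
            np.testing.assert_allclose(build_gldm(d),
                                       naive_gldm(d.level_image, d.mask, d.n_levels))
            got = build_ngtdm(d)
            expected = naive_ngtdm(d.level_image, d.mask, d.n_levels)
            for key in ("n", "p", "s"):
                np.testing.assert_allclose(got[key], expected[key], atol=1e-12)
            assert got["n_valid"] == expected["n_valid"]

    def test_matrix_normalizations(self, rng):
        d = random_discretized_roi(rng)
        for mat in build_glcm(d):
            assert mat.sum() == pytest.approx(1.0)
        stats = build_ngtdm(d)
        if stats["n_valid"]:
            assert stats["p"].sum() == pytest.approx(1.0)
        assert build_gldm(d).sum() == d.roi_pixel_count


class TestFirstOrder:
    def test_constant_roi_closed_forms(self):
        n = 9
        d = discretize_roi(np.full((3, 3), 6.0), np.ones((3, 3), bool), 25.0)
        out = firstorder_features(d.original_values, d, pixel_area=1.0)
        assert out["Mean"] == out["Median"] == out["Minimum"] == out["Maximum"] == 6.0
        assert out["Variance"] == 0.0
        assert out["Uniformity"] == 1.0
        assert out["Energy"] == n * 36.0
        assert out["Skewness"] == 0.0 and out["Kurtosis"] == 0.0

    def test_hand_computed_four_values(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0]])
        d = discretize_roi(values, np.ones((1, 4), bool), 1.0)
        out = firstorder_features(d.original_values, d, pixel_area=1.0)
        assert out["Mean"] == 2.5
        assert out["Range"] == 3.0
        assert out["Variance"] == 1.25  # population convention

    def test_matches_definition_literal_loop(self, rng):
        values = rng.normal(100, 30, size=1000)
        mask = np.ones((1000, 1), bool)
        d = discretize_roi(values.reshape(-1, 1), mask, bin_width=10.0)
        fast = firstorder_features(d.original_values, d, pixel_area=1.0)
        slow = naive_firstorder(d.original_values, d.levels, d.n_levels, pixel_area=1.0)
        for name, expected in slow.items():
            assert fast[name] == pytest.approx(expected, rel=1e-9), name


class TestFamilyFeatures:
    def test_single_level_glcm_degenerate_values(self):
        out = glcm_features([np.array([[1.0]])])
        assert out["Contrast"] == 0.0
        assert out["Correlation"] == 1.0  # zero-variance fallback
        assert out["JointEntropy"] == 0.0

    def test_single_run_nonuniformities_are_one(self):
        mat = np.zeros((2, 4))
        mat[1, 2] = 1  # a single run
        out = glrlm_features([mat], n_pixels=3)
        assert out["GrayLevelNonUniformity"] == 1.0
        assert out["RunLengthNonUniformity"] == 1.0

    def test_all_family_features_match_naive_formulas(self, rng):
        # definition-literal check of all 75 matrix-family features
        for _ in range(20):
            d = random_discretized_roi(rng)
            glcm_mats = build_glcm(d)
            fast = glcm_features(glcm_mats)
            slow = {}
            per_dir = [naive_glcm_features(m) for m in glcm_mats]
            for key in per_dir[0]:
                slow[key] = float(np.mean([v[key] for v in per_dir]))
            for name in slow:
                assert fast[name] == pytest.approx(slow[name], rel=1e-9, abs=1e-12), name

            rl = build_glrlm(d)
            fast = glrlm_features(rl, d.roi_pixel_count)
            per_dir = [naive_glrlm_features(m, d.roi_pixel_count) for m in rl]
            for name in per_dir[0]:
                expected = float(np.mean([v[name] for v in per_dir]))
                assert fast[name] == pytest.approx(expected, rel=1e-9), name

            fast = glszm_features(build_glszm(d), d.roi_pixel_count)
            slow = naive_glszm_features(
                naive_glszm(d.level_image, d.mask, d.n_levels), d.roi_pixel_count)
            for name in slow:
                assert fast[name] == pytest.approx(slow[name], rel=1e-9), name

            fast = gldm_features(build_gldm(d))
            slow = naive_gldm_features(naive_gldm(d.level_image, d.mask, d.n_levels))
            for name in slow:
                assert fast[name] == pytest.approx(slow[name], rel=1e-9), name

            stats = build_ngtdm(d)
            if stats["n_valid"] == 0:
                continue
            fast = ngtdm_features(stats)
            slow = naive_ngtdm_features(naive_ngtdm(d.level_image, d.mask, d.n_levels))
            for name in slow:
                assert fast[name] == pytest.approx(slow[name], rel=1e-9, abs=1e-12), name


class TestExtractAll:
    def test_full_vector_has_1023_named_values(self, small_map):
        pmap, mask = small_map
        fv = extract_all(pmap, mask)
        assert len(fv) == 1023
        manifest = feature_manifest()
        assert sorted(fv.values) == sorted(manifest["full_names"])
        for label in FILTER_LABELS:
            per_version = [n for n in fv.values if n.startswith(label + "_")]
            assert len(per_version) == 93
        for cls, count in FEATURE_CLASS_COUNTS.items():
            per_class = [n for n in fv.values if f"_{cls}_" in n]
            assert len(per_class) == count * 11

    def test_identical_masks_give_identical_vectors(self, small_map):
        pmap, mask = small_map
        f1 = extract_all(pmap, mask)
        f2 = extract_all(pmap, BinaryMask(mask.grid.copy(), mask.pixel_spacing))
        assert f1.values == f2.values

    def test_translation_leaves_firstorder_unchanged(self, small_spec):
        # shifting map and mask together moves the ROI but not its contents
        pmap, mask = generate_map(small_spec, 8.0, seed=21)
        shift = 3
        values = np.roll(pmap.values, shift, axis=0)
        grid = np.roll(mask.grid, shift, axis=0)
        f_ref = extract_all(pmap, mask)
        f_shift = extract_all(ParametricMap(values, pmap.pixel_spacing),
                              BinaryMask(grid, mask.pixel_spacing))
        for name, val in f_ref.values.items():
            if "_firstorder_" in name and "wavelet" not in name:
                assert f_shift[name] == pytest.approx(val, rel=1e-9), name

    def test_lbp_maximum_saturates_at_code_bound(self, small_map):
        pmap, mask = small_map
        fv = extract_all(pmap, mask)
        # 9 samples -> rotation-invariant uniform codes top out at 10
        assert fv["lbp-2D_firstorder_Maximum"] == 10.0
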