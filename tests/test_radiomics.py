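import numpy as np
import pytest
from scipy import stats

from oracles import (
    brute_glcm,
    brute_gldm,
    brute_glrlm,
    brute_glszm,
    matrix_to_dict,
    random_roi,
)
from phantomrad import VoxelVolume
from phantomrad.radiomics import (
    CANONICAL_NAMES,
    ExtractionConfig,
    FAMILY_COUNTS,
    discretise,
    extract_features,
    family_of,
    first_order_features,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
)


class TestDiscretise:
    def test_floor_formula_hand_example(self):
        v = np.array([100.0, 124.0, 125.0, 150.0]).reshape(4, 1, 1)
        disc = discretise(v, np.ones((4, 1, 1), bool), 25.0)
        assert disc.levels.ravel().tolist() == [1, 1, 2, 3]
        assert disc.n_levels == 3

    def test_constant_roi_single_level(self):
        disc = discretise(np.full((3, 3, 3), 42.0), np.ones((3, 3, 3), bool))
        assert disc.n_levels == 1
        assert np.all(disc.levels[disc.mask] == 1)

    def test_default_bin_width_is_25(self):
        v = np.array([0.0, 25.0]).reshape(2, 1, 1)
        disc = discretise(v, np.ones((2, 1, 1), bool))
        assert disc.bin_width == 25.0
        assert disc.n_levels == 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretise(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))

    def test_levels_anchored_at_roi_minimum(self, rng):
        v = rng.normal(0, 100, (5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.6
        mask.flat[0] = True
        disc = discretise(v, mask, 25.0)
        assert disc.levels[disc.mask].min() == 1


class TestMatrixExamples:
    def test_glcm_1x3_line(self):
        v = np.array([0.0, 30.0, 0.0]).reshape(1, 3, 1)
        disc = discretise(v, np.ones((1, 3, 1), bool), 25.0)
        m = glcm_matrix(disc)
        np.testing.assert_array_equal(m, [[0, 2], [2, 0]])
        p = m / m.sum()
        assert p[0, 1] == pytest.approx(0.5)

    def test_glcm_symmetric(self, rng):
        for _ in range(10):
            values, mask = random_roi(rng)
            disc = discretise(values, mask, 25.0)
            m = glcm_matrix(disc)
            np.testing.assert_array_equal(m, m.T)

    def test_glszm_2x2_single_zone(self):
        disc = discretise(np.zeros((2, 2, 1)), np.ones((2, 2, 1), bool))
        m = glszm_matrix(disc)
        assert matrix_to_dict(m) == {(1, 4): 1.0}

    def test_single_voxel_degenerate(self):
        disc = discretise(np.zeros((1, 1, 1)), np.ones((1, 1, 1), bool))
        assert matrix_to_dict(glrlm_matrix(disc)) == {(1, 1): 13.0}
        assert matrix_to_dict(glszm_matrix(disc)) == {(1, 1): 1.0}
        # zero dependent neighbours -> dependence size 1
        assert matrix_to_dict(gldm_matrix(disc)) == {(1, 1): 1.0}
        assert glcm_matrix(disc).sum() == 0


class TestBruteForceOracles:
    """Exhaustive enumeration oracles on randomized small ROIs."""

    N_CASES = 30

    def _cases(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(self.N_CASES):
            values, mask = random_roi(rng, max_side=4, n_levels=3)
            yield values, mask, discretise(values, mask, 25.0)

    def test_glcm_matches_enumeration(self):
        for values, mask, disc in self._cases(101):
            got = matrix_to_dict(glcm_matrix(disc))
            expected = brute_glcm(disc.levels, disc.mask)
            assert got == expected, f"shape={values.shape}"

    def test_glrlm_matches_enumeration(self):
        for values, mask, disc in self._cases(102):
            got = matrix_to_dict(glrlm_matrix(disc))
            expected = brute_glrlm(disc.levels, disc.mask)
            assert got == expected

    def test_glszm_matches_enumeration(self):
        for values, mask, disc in self._cases(103):
            got = matrix_to_dict(glszm_matrix(disc))
            expected = brute_glszm(disc.levels, disc.mask)
            assert got == expected

    def test_gldm_matches_enumeration(self):
        for values, mask, disc in self._cases(104):
            got = matrix_to_dict(gldm_matrix(disc))
            expected = brute_gldm(disc.levels, disc.mask)
            assert got == expected


class TestConservationLaws:
    def test_glcm_pair_count(self, rng):
        for _ in range(10):
            values, mask, = random_roi(rng)
            disc = discretise(values, mask, 25.0)
            # symmetrised aggregate counts every unordered valid pair twice
            n_pairs = sum(brute_glcm(disc.levels, disc.mask).values())
            assert glcm_matrix(disc).sum() == n_pairs

    def test_glszm_voxel_conservation(self, rng):
        for _ in range(10):
            values, mask = random_roi(rng)
            disc = discretise(values, mask, 25.0)
            m = glszm_matrix(disc)
            sizes = np.arange(1, m.shape[1] + 1)
            assert (m * sizes).sum() == disc.n_voxels

    def test_glrlm_voxel_conservation(self, rng):
        for _ in range(10):
            values, mask = random_roi(rng)
            disc = discretise(values, mask, 25.0)
            m = glrlm_matrix(disc)
            lengths = np.arange(1, m.shape[1] + 1)
            # each of the 13 directions partitions the ROI into runs
            assert (m * lengths).sum() == 13 * disc.n_voxels

    def test_gldm_voxel_conservation(self, rng):
        for _ in range(10):
            values, mask = random_roi(rng)
            disc = discretise(values, mask, 25.0)
            assert gldm_matrix(disc).sum() == disc.n_voxels


class TestFirstOrder:
    def test_constant_roi_closed_forms(self):
        n = 27
        c = 7.0
        values = np.full((3, 3, 3), c)
        mask = np.ones((3, 3, 3), bool)
        f = first_order_features(values, mask)
        assert f["Mean"] == c
        assert f["Variance"] == 0.0
        assert f["Energy"] == pytest.approx(n * c**2)
        assert f["Entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["Uniformity"] == pytest.approx(1.0)
        assert f["Range"] == 0.0

    def test_hand_arithmetic(self):
        values = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        f = first_order_features(values, np.ones((4, 1, 1), bool))
        assert f["Mean"] == 2.5
        assert f["Range"] == 3.0
        assert f["Median"] == 2.5
        assert f["Minimum"] == 1.0
        assert f["Maximum"] == 4.0

    def test_against_independent_reference(self, rng):
        # scipy/numpy closed forms as the independent route
        values = rng.normal(50, 30, (6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.7
        mask[0, 0, 0] = True
        x = values[mask]
        f = first_order_features(values, mask, spacing=(1.5, 1.5, 2.0))
        rel = lambda a, b: abs(a - b) / max(abs(b), 1e-12)
        assert rel(f["Mean"], x.mean()) < 1e-6
        assert rel(f["Variance"], x.var()) < 1e-6
        assert rel(f["Skewness"], stats.skew(x)) < 1e-6
        assert rel(f["Kurtosis"], stats.kurtosis(x, fisher=False)) < 1e-6
        assert rel(f["Energy"], (x**2).sum()) < 1e-6
        assert rel(f["TotalEnergy"], 1.5 * 1.5 * 2.0 * (x**2).sum()) < 1e-6
        assert rel(f["RootMeanSquared"], np.sqrt((x**2).mean())) < 1e-6
        assert rel(f["10Percentile"], np.percentile(x, 10)) < 1e-6
        assert rel(f["90Percentile"], np.percentile(x, 90)) < 1e-6
        assert rel(f["InterquartileRange"],
                   np.percentile(x, 75) - np.percentile(x, 25)) < 1e-6
        assert rel(f["MeanAbsoluteDeviation"], np.abs(x - x.mean()).mean()) < 1e-6
        sub = x[(x >= np.percentile(x, 10)) & (x <= np.percentile(x, 90))]
        assert rel(f["RobustMeanAbsoluteDeviation"],
                   np.abs(sub - sub.mean()).mean()) < 1e-6

    def test_voxel_array_shift_enters_energy_only(self, rng):
        values = rng.normal(0, 10, (4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        f0 = first_order_features(values, mask, voxel_array_shift=0.0)
        f1 = first_order_features(values, mask, voxel_array_shift=100.0)
        assert f0["Mean"] == f1["Mean"]
        assert f0["Variance"] == f1["Variance"]
        assert f1["Energy"] > f0["Energy"]


class TestExtractFeatures:
    def test_census_86_with_family_counts(self, rng):
        vol = VoxelVolume(rng.normal(50, 30, (16, 16, 16)))
        mask = np.zeros((16, 16, 16), bool)
        mask[2:14, 2:14, 2:14] = True
        fv = extract_features(vol, mask)
        assert len(fv) == 86
        counts = {}
        for name in fv.values:
            counts[family_of(name)] = counts.get(family_of(name), 0) + 1
        assert counts == FAMILY_COUNTS

    def test_canonical_order(self, rng):
        vol = VoxelVolume(rng.normal(0, 40, (8, 8, 8)))
        fv = extract_features(vol, np.ones((8, 8, 8), bool))
        assert tuple(fv.values.keys()) == CANONICAL_NAMES

    def test_constant_shift_invariance(self, rng):
        # min-anchored binning: texture features unchanged, locations shift
        values = rng.normal(100, 40, (8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        f0 = extract_features(VoxelVolume(values), mask)
        f1 = extract_features(VoxelVolume(values + 200.0), mask)
        for name in CANONICAL_NAMES:
            if name.startswith(("glcm", "gldm", "glrlm", "glszm")):
                assert f1.values[name] == pytest.approx(
                    f0.values[name], rel=1e-12
                ), name
        assert f1.values["firstorder_Mean"] == pytest.approx(
            f0.values["firstorder_Mean"] + 200.0
        )
        assert f1.values["firstorder_Median"] == pytest.approx(
            f0.values["firstorder_Median"] + 200.0
        )
        assert f1.values["firstorder_Variance"] == pytest.approx(
            f0.values["firstorder_Variance"], rel=1e-9
        )

    def test_all_finite_on_valid_roi(self, small_phantom):
        _, volume, masks = small_phantom
        for m in masks:
            fv = extract_features(volume, m)
            assert all(np.isfinite(v) for v in fv.values.values()), m.name

    def test_degenerate_single_level_roi_finite(self):
        vol = VoxelVolume(np.full((4, 4, 4), 5.0))
        fv = extract_features(vol, np.ones((4, 4, 4), bool))
        assert all(np.isfinite(v) for v in fv.values.values())
        assert fv.values["glcm_Correlation"] == 0.0  # degenerate convention

    def test_boundary_roi_handled(self, rng):
        # mask touching the volume boundary: outside neighbours absent
        vol = VoxelVolume(rng.normal(0, 40, (5, 5, 5)))
        mask = np.ones((5, 5, 5), bool)
        fv = extract_features(vol, mask)
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_roi_metadata_propagated(self, small_phantom):
        _, volume, masks = small_phantom
        fv = extract_features(volume, masks[0], acquisition_id="acq7")
        assert fv.roi_name == masks[0].name
        assert fv.tissue_class == masks[0].tissue_class
        assert fv.acquisition_id == "acq7"
        row = fv.as_row()
        assert row["roi"] == masks[0].name
        assert len([k for k in row if k in CANONICAL_NAMES]) == 86

    def test_mask_volume_mismatch_rejected(self, rng):
        vol = VoxelVolume(rng.normal(0, 1, (4, 4, 4)))
        with pytest.raises(ValueError, match="congruent"):
            extract_features(vol, np.ones((5, 5, 5), bool))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="bin_width"):
            ExtractionConfig(bin_width=0)
        with pytest.raises(ValueError, match="neighbor_distance"):
            ExtractionConfig(neighbor_distance=0)
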