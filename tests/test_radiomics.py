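import numpy as np
import pandas as pd
import pytest

from habhet.habitats import encode_habitats
from habhet.io import SEQUENCES, VolumeStack, normalize_stack
from habhet.radiomics import (
    FEATURE_CLASSES,
    N_FEATURES,
    extract_features,
    extract_per_habitat,
    extract_whole_region,
    feature_manifest,
    firstorder_features,
    shape_features,
)


class TestManifest:
    def test_class_counts_sum_to_107(self):
        counts = {cls: len(names) for cls, names in FEATURE_CLASSES.items()}
        assert counts == {"firstorder": 18, "shape": 14, "glcm": 24,
                          "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}
        assert N_FEATURES == 107
        assert len(set(feature_manifest())) == 107


class TestFirstOrder:
    def test_hand_computed_2x2x1_roi(self):
        # intensities {1, 1, 2, 3}: mean 1.75, energy 1+1+4+9 = 15
        vol = np.zeros((2, 2, 1))
        vol[:, :, 0] = [[1, 1], [2, 3]]
        roi = np.ones((2, 2, 1), bool)
        out = extract_features(vol, roi, spacing=(1, 1, 1))
        assert out["firstorder_Mean"] == pytest.approx(1.75)
        assert out["firstorder_Energy"] == pytest.approx(15.0)
        assert out["firstorder_Minimum"] == 1.0
        assert out["firstorder_Maximum"] == 3.0

    def test_constant_roi_zero_dispersion(self):
        vol = np.full((4, 4, 2), 5.0)
        out = extract_features(vol, np.ones(vol.shape, bool), (1, 1, 1))
        assert out["firstorder_Variance"] == 0.0
        assert out["firstorder_Range"] == 0.0

    def test_statistics_against_numpy(self, rng):
        x = rng.normal(2, 3, 500)
        out = firstorder_features(x, voxel_volume=1.0)
        assert out["Mean"] == pytest.approx(x.mean())
        assert out["Variance"] == pytest.approx(x.var())
        assert out["Median"] == pytest.approx(np.median(x))
        assert out["RootMeanSquared"] == pytest.approx(np.sqrt((x**2).mean()))


class TestShape:
    def test_voxel_volume_and_cube_surface(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True  # 4x4x4 cube, unit spacing
        out = shape_features(mask, (1, 1, 1))
        assert out["VoxelVolume"] == pytest.approx(64.0)
        # the marching-cubes surface of a voxelized cube lies between the
        # inscribed (3^2*6=54) and circumscribed (4^2*6=96) hull areas
        assert 54 <= out["SurfaceArea"] <= 96
        assert out["MeshVolume"] <= 64.0
        assert out["Sphericity"] < 1.0

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        iso = shape_features(mask, (1, 1, 1))
        aniso = shape_features(mask, (1, 1, 3))
        assert aniso["VoxelVolume"] == pytest.approx(3 * iso["VoxelVolume"])

    def test_elongation_of_a_rod(self):
        mask = np.zeros((20, 4, 4), bool)
        mask[2:18, 1:3, 1:3] = True
        out = shape_features(mask, (1, 1, 1))
        assert out["MajorAxisLength"] > out["MinorAxisLength"]
        assert out["Elongation"] < 0.5


class TestExtraction:
    def test_output_has_107_names(self, phantom_case):
        stack = normalize_stack(phantom_case["stack"])
        tumor = phantom_case["masks"]["tumor_obs1"]
        out = extract_features(stack.volumes["AP"], tumor, stack.spacing)
        assert len(out) == 107
        assert set(out) == set(feature_manifest())

    def test_whole_region_428_values(self, phantom_case):
        stack = normalize_stack(phantom_case["stack"])
        out = extract_whole_region(stack, phantom_case["masks"]["tumor_obs1"])
        assert len(out) == 428
        # shape features replicate across sequences
        for name in FEATURE_CLASSES["shape"]:
            vals = {out[f"{seq}_shape_{name}"] for seq in SEQUENCES}
            assert len(vals) == 1

    def test_tiny_roi_texture_missing_firstorder_present(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((6, 6, 3))
        roi = np.zeros(vol.shape, bool)
        roi[2, 2, 1] = roi[2, 3, 1] = True  # 2 voxels
        out = extract_features(vol, roi, (1, 1, 3))
        assert np.isfinite(out["firstorder_Mean"])
        assert np.isnan(out["glcm_Contrast"])
        assert np.isnan(out["ngtdm_Coarseness"])

    def test_translation_invariance_of_intensity_features(self):
        rng = np.random.default_rng(5)
        patch = rng.standard_normal((5, 5, 3))
        vol1 = np.zeros((14, 14, 8))
        vol2 = np.zeros((14, 14, 8))
        vol1[2:7, 2:7, 1:4] = patch
        vol2[6:11, 5:10, 3:6] = patch
        roi1 = np.zeros(vol1.shape, bool)
        roi2 = np.zeros(vol2.shape, bool)
        roi1[2:7, 2:7, 1:4] = True
        roi2[6:11, 5:10, 3:6] = True
        out1 = extract_features(vol1, roi1, (1, 1, 3))
        out2 = extract_features(vol2, roi2, (1, 1, 3))
        for key in out1:
            if key.startswith("shape_"):
                continue
            np.testing.assert_allclose(out1[key], out2[key], rtol=1e-10,
                                       err_msg=key)

    def test_determinism(self, phantom_case):
        stack = normalize_stack(phantom_case["stack"])
        tumor = phantom_case["masks"]["tumor_obs1"]
        a = extract_features(stack.volumes["T2"], tumor, stack.spacing)
        b = extract_features(stack.volumes["T2"], tumor, stack.spacing)
        assert a == b

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestPerHabitat:
    def test_table_shape_and_single_habitat_identity(self, normalized_case):
        stack, tumor = normalized_case
        hm = encode_habitats(stack, tumor, K=1)
        table = extract_per_habitat(stack, hm)
        assert table.shape == (1, 428)
        whole = extract_whole_region(stack, tumor)
        row = table.iloc[0]
        pd.testing.assert_series_equal(row[whole.index], whole,
                                       check_names=False, rtol=1e-10)
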