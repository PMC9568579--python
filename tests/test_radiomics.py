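"""Radiomics core: discretization, first-order, shape, GLCM and GLDM."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radhet.catalog import catalog
from radhet.errors import DegenerateLesionError, UnsupportedFeatureError
from radhet.radiomics import (
    DiscretizedROI,
    discretize_fbw,
    extract_features,
    glcm_features,
    gldm_features,
    percentile_90,
    resample_isotropic,
    shape_features,
    sphericity_from_mesh,
)
from radhet.synthetic import LesionGenParams, generate_lesion

from conftest import random_roi
from oracles import glcm_oracle, gldm_oracle


def digital_sphere(radius, spacing=1.0, pad=2):
    n = int(np.ceil(radius / spacing)) + pad
    ax = (np.arange(2 * n + 1) - n) * spacing
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= radius**2


class TestCatalog:
    def test_total_and_class_counts(self):
        cat = catalog()
        assert len(cat) == 107
        assert cat.class_counts() == {
            "firstorder": 18, "shape": 14, "glcm": 24, "glrlm": 16,
            "glszm": 16, "ngtdm": 5, "gldm": 14,
        }

    def test_native_flags(self):
        cat = catalog()
        native = cat.native_names()
        assert len(native) == 9
        assert "shape_VoxelVolume" in native
        assert "shape_MeshVolume" in native
        assert "glcm_Imc1" in native


class TestDiscretize:
    def test_hand_computed_bins(self):
        d = discretize_fbw(np.array([0.0, 5.0, 10.0, 25.0]),
                           np.ones(4, bool), 10.0)
        assert d.levels.tolist() == [1, 1, 2, 3]
        assert d.n_levels == 3

    def test_constant_roi_single_bin(self):
        d = discretize_fbw(np.full((2, 2, 2), 7.0), np.ones((2, 2, 2), bool))
        assert d.n_levels == 1
        assert np.all(d.levels == 1)

    @given(shift=st.floats(-1e4, 1e4, allow_nan=False))
    def test_shift_invariance(self, shift):
        vals = np.array([3.0, 17.0, 42.0, 58.0, 99.0])
        mask = np.ones(5, bool)
        base = discretize_fbw(vals, mask).levels
        shifted = discretize_fbw(vals + shift, mask).levels
        assert np.array_equal(base, shifted)

    def test_bad_width(self):
        with pytest.raises(ValueError):
            discretize_fbw(np.ones(3), np.ones(3, bool), 0.0)


class TestPercentile:
    @pytest.mark.parametrize("values,expected", [
        (np.arange(1, 11), 9.1),       # linear interpolation between 9 and 10
        (np.full(6, 3.5), 3.5),        # constant ROI
        (np.array([42.0]), 42.0),      # single voxel
    ])
    def test_values(self, values, expected):
        assert percentile_90(values) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(DegenerateLesionError):
            percentile_90(np.array([]))


class TestShape:
    def test_voxel_volume_counts_voxels(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, :2] = True
        mask[1, :2, 1] = True
        assert mask.sum() == 3
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["shape_VoxelVolume"] == pytest.approx(3.0)

    def test_unit_cube_sphericity_closed_form(self):
        assert sphericity_from_mesh(1.0, 6.0) == pytest.approx(
            (36 * math.pi) ** (1 / 3) / 6
        )

    def test_digitized_sphere(self):
        mask = digital_sphere(10.0)
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["shape_Sphericity"] == pytest.approx(1.0, abs=0.02)
        assert f["shape_Maximum2DDiameterSlice"] == pytest.approx(20.0, rel=0.05)

    def test_sphericity_approaches_one_monotonically(self):
        values = [shape_features(digital_sphere(r), (1.0,) * 3)["shape_Sphericity"]
                  for r in (5.0, 10.0, 20.0)]
        assert values[0] <= values[1] <= values[2] <= 1.0

    def test_isotropic_scaling_leaves_sphericity(self):
        mask = digital_sphere(6.0)
        s1 = shape_features(mask, (1.0, 1.0, 1.0))["shape_Sphericity"]
        s2 = shape_features(mask, (2.0, 2.0, 2.0))["shape_Sphericity"]
        assert s1 == pytest.approx(s2, rel=1e-6)

    def test_single_voxel_uses_cuboid(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["shape_MeshVolume"] == pytest.approx(1.0)
        assert f["shape_Sphericity"] == pytest.approx(
            (36 * math.pi) ** (1 / 3) / 6
        )


class TestGLCM:
    def test_constant_roi_degenerate_convention(self):
        d = discretize_fbw(np.full((2, 2, 2), 5.0), np.ones((2, 2, 2), bool))
        f = glcm_features(d)
        assert f["glcm_Imc1"] == 0.0
        assert f["glcm_Idmn"] == 1.0

    def test_2x2_roi_matches_pair_enumeration(self):
        levels = np.array([[[1, 1], [1, 2]]])
        mask = np.ones((1, 2, 2), bool)
        d = DiscretizedROI(levels, mask, 10.0, 2)
        f = glcm_features(d)
        o = glcm_oracle(levels, mask)
        assert f["glcm_Imc1"] == pytest.approx(o["imc1"])
        assert f["glcm_Idmn"] == pytest.approx(o["idmn"])

    def test_idmn_bounded(self, rng):
        for _ in range(20):
            levels, mask = random_roi(rng)
            d = DiscretizedROI(levels, mask, 10.0, int(levels[mask].max()))
            f = glcm_features(d)
            assert 0.0 < f["glcm_Idmn"] <= 1.0 + 1e-12


class TestGLDM:
    def test_hand_enumerated_2x2(self):
        levels = np.array([[[1, 1], [1, 2]]])
        mask = np.ones((1, 2, 2), bool)
        d = DiscretizedROI(levels, mask, 10.0, 2)
        f = gldm_features(d, alpha=0)
        assert f["gldm_LargeDependenceEmphasis"] == pytest.approx(7.0)
        assert f["gldm_LargeDependenceHighGrayLevelEmphasis"] == pytest.approx(7.75)
        assert f["gldm_DependenceVariance"] == pytest.approx(0.75)

    def test_constant_mutually_adjacent_block_zero_variance(self):
        # in a 2x2x2 block every voxel is a 26-neighbor of every other, so a
        # constant ROI has a single dependence size (k=8) and zero variance
        d = discretize_fbw(np.full((2, 2, 2), 2.0), np.ones((2, 2, 2), bool))
        f = gldm_features(d)
        assert f["gldm_LargeDependenceEmphasis"] == pytest.approx(64.0)
        assert f["gldm_DependenceVariance"] == pytest.approx(0.0)

    def test_constant_larger_block_matches_neighbor_count_oracle(self):
        # larger constant blocks have boundary voxels with fewer neighbors,
        # so the dependence size varies; the brute-force count is the truth
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones((3, 3, 3), bool)
        d = DiscretizedROI(levels, mask, 10.0, 1)
        f = gldm_features(d)
        o = gldm_oracle(levels, mask)
        assert f["gldm_DependenceVariance"] == pytest.approx(
            o["dependence_variance"])


class TestTextureOracleEquivalence:
    """Both texture classes against brute-force enumeration on random ROIs."""

    def test_glcm_gldm_match_bruteforce_on_small_rois(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            levels, mask = random_roi(rng)
            d = DiscretizedROI(levels, mask, 10.0, int(levels[mask].max()))
            g = glcm_features(d)
            og = glcm_oracle(levels, mask)
            assert g["glcm_Imc1"] == pytest.approx(og["imc1"], abs=1e-10)
            assert g["glcm_Idmn"] == pytest.approx(og["idmn"], abs=1e-10)
            f = gldm_features(d)
            of = gldm_oracle(levels, mask)
            assert f["gldm_LargeDependenceEmphasis"] == pytest.approx(of["lde"])
            assert f["gldm_LargeDependenceHighGrayLevelEmphasis"] == \
                pytest.approx(of["ldhgle"])
            assert f["gldm_DependenceVariance"] == \
                pytest.approx(of["dependence_variance"])


class TestResample:
    def test_identity_when_already_isotropic(self):
        img = np.random.default_rng(0).normal(size=(5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        out_img, out_mask, sp = resample_isotropic(img, mask, (1.0, 1.0, 1.0))
        assert np.allclose(out_img, img, atol=1e-6)
        assert np.array_equal(out_mask, mask)

    def test_constant_field_preserved(self):
        img = np.full((6, 6, 6), 5.0)
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        out_img, out_mask, _ = resample_isotropic(img, mask, (2.0, 2.0, 2.0))
        assert np.allclose(out_img, 5.0)

    def test_sphere_volume_conserved(self):
        ax = (np.arange(14) - 6.5) * 2.0
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = zz**2 + yy**2 + xx**2 <= 100.0
        img = np.where(mask, 50.0, 0.0)
        _, out_mask, _ = resample_isotropic(img, mask, (2.0, 2.0, 2.0))
        pre_volume = mask.sum() * 8.0
        assert out_mask.sum() == pytest.approx(pre_volume, rel=0.05)


class TestExtractFeatures:
    def test_robust8_finite_on_synthetic_lesion(self, rng):
        lesion = generate_lesion(LesionGenParams(), rng=rng)
        fv = extract_features(lesion.image, lesion.mask, lesion.spacing,
                              resample=False)
        assert len(fv.values) == 8
        assert all(np.isfinite(v) for v in fv.values.values())
        assert fv.provenance == "native"

    def test_zero_noise_sphere_degenerate_texture(self):
        lesion = generate_lesion(
            LesionGenParams(radii_mm=(8.0, 8.0, 8.0), surface_noise=0.0,
                            intensity_sd=0.0), rng=0)
        fv = extract_features(lesion.image, lesion.mask, lesion.spacing,
                              resample=False)
        assert fv["shape_Sphericity"] == pytest.approx(1.0, abs=0.02)
        # constant intensity: single gray level, degenerate GLCM conventions
        assert fv["glcm_Imc1"] == 0.0
        # dependence variance reduces to the variance of the in-mask
        # neighbor counts — the brute-force oracle is the reference
        from radhet.radiomics import discretize_fbw

        disc = discretize_fbw(lesion.image, lesion.mask)
        o = gldm_oracle(disc.levels, lesion.mask)
        assert fv["gldm_DependenceVariance"] == pytest.approx(
            o["dependence_variance"])

    def test_deterministic(self):
        lesion = generate_lesion(LesionGenParams(), rng=3)
        a = extract_features(lesion.image, lesion.mask, lesion.spacing,
                             resample=False)
        b = extract_features(lesion.image, lesion.mask, lesion.spacing,
                             resample=False)
        assert a.values == b.values

    def test_intensity_shift_leaves_texture(self):
        lesion = generate_lesion(LesionGenParams(), rng=5)
        a = extract_features(lesion.image, lesion.mask, lesion.spacing,
                             resample=False)
        b = extract_features(lesion.image + 1000.0, lesion.mask,
                             lesion.spacing, resample=False)
        for name in ("glcm_Imc1", "gldm_LargeDependenceEmphasis",
                     "gldm_DependenceVariance"):
            assert a[name] == pytest.approx(b[name])

    def test_unsupported_feature_errors(self):
        lesion = generate_lesion(LesionGenParams(), rng=1)
        with pytest.raises(UnsupportedFeatureError):
            extract_features(lesion.image, lesion.mask, lesion.spacing,
                             features=["glrlm_RunEntropy"])
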