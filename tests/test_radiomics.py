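"""Quantization, texture matrices/features, shape descriptors, AWS, vector."""

import numpy as np
import pytest

from ebusml.radiomics import (FEATURE_NAMES, QuantizationSpec, assemble_vector,
                              aws_feature, glcm, quantize, radiomics_features,
                              shape2d_features, texture_features)
from ebusml.radiomics.matrices import GLCM_ANGLES
from ebusml.types import PatientRecord

import reference_textures as ref


RECORD = PatientRecord(gender="female", smoking="ex-smoker", age=55.0,
                       lesion_size="<3cm", label=0, id="r")


class TestQuantize:
    def test_constant_region_all_level_one(self):
        q = quantize(np.full((5, 5), 9.0), np.ones((5, 5), bool))
        assert set(q.ravel()) == {1}

    def test_two_values_two_levels(self):
        arr = np.array([[0.0, 255.0], [255.0, 0.0]])
        q = quantize(arr, np.ones((2, 2), bool), QuantizationSpec(2))
        assert set(q.ravel()) == {1, 2}

    def test_linear_ramp_equal_width_bins(self):
        arr = np.linspace(0, 255, 3200).reshape(32, 100)
        q = quantize(arr, np.ones_like(arr, bool), QuantizationSpec(32))
        # direct bin-edge oracle
        expect = np.minimum(np.floor((arr - arr.min()) / np.ptp(arr) * 32) + 1, 32)
        assert np.array_equal(q, expect.astype(int))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestGlcm:
    def test_hand_counted_horizontal_pairs(self):
        grid = np.array([[1, 1], [2, 2]])
        m = glcm(grid, (0, 1), n_levels=2)
        assert np.array_equal(m.counts, np.array([[2.0, 0.0], [0.0, 2.0]]))

    def test_checkerboard_zero_diagonal(self):
        grid = np.indices((6, 6)).sum(axis=0) % 2 + 1
        m = glcm(grid, (0, 1), n_levels=2)
        assert m.counts[0, 0] == 0 and m.counts[1, 1] == 0
        from ebusml.radiomics.features import glcm_features
        f = glcm_features(m.normalized)
        assert f["glcm_contrast"] == pytest.approx(1.0)  # max for 2 levels

    def test_normalized_sums_to_one_and_symmetric(self, rng):
        grid = rng.integers(1, 4, size=(8, 8))
        m = glcm(grid, (-1, 1), n_levels=3)
        assert m.normalized.sum() == pytest.approx(1.0)
        assert np.array_equal(m.counts, m.counts.T)

    def test_small_mask_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.array([[1, 0], [0, 0]]), (0, 1))


class TestDegenerateRegion:
    def test_constant_region_conventions(self):
        q = np.ones((6, 6), dtype=int)
        f = texture_features(q, n_levels=32)
        assert f["glcm_joint_energy"] == pytest.approx(1.0)
        assert f["glcm_joint_entropy"] == pytest.approx(0.0)
        assert f["glcm_contrast"] == pytest.approx(0.0)
        assert f["glcm_correlation"] == 0.0           # documented convention
        # a single run set per direction: one 6-long run per row at 0 deg
        assert f["glrlm_long_run_emphasis"] > 1.0
        assert np.isfinite(list(f.values())).all()


class TestBruteForceAgreement:
    @pytest.mark.parametrize("trial", range(10))
    def test_all_families_match_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        q = rng.integers(1, 4, size=(6, 6))
        if trial % 3 == 0:  # also exercise mask breaks
            q[rng.random(q.shape) < 0.2] = 0
        ng = 3
        ours = texture_features(q, n_levels=ng)
        nvox = int((q > 0).sum())

        glcm_ref, glrlm_ref = {}, {}
        for off in GLCM_ANGLES.values():
            f = ref.ref_glcm_features(ref.ref_glcm_counts(q, off))
            for k, v in f.items():
                glcm_ref[k] = glcm_ref.get(k, 0.0) + v / 4
            fr = ref.ref_rlm_style_features(ref.ref_glrlm(q, off), nvox,
                                            "glrlm", ref.GLRLM_NAMES)
            for k, v in fr.items():
                glrlm_ref[k] = glrlm_ref.get(k, 0.0) + v / 4
        expected = dict(glcm_ref)
        expected.update(glrlm_ref)
        expected.update(ref.ref_rlm_style_features(ref.ref_glszm(q), nvox,
                                                   "glszm", ref.GLSZM_NAMES))
        expected.update(ref.ref_rlm_style_features(ref.ref_gldm(q), nvox,
                                                   "gldm", ref.GLDM_NAMES))
        expected.update(ref.ref_ngtdm_features(q))
        for name, val in expected.items():
            assert ours[name] == pytest.approx(val, abs=1e-9), name


class TestRotationConsistency:
    def test_angle_averaged_features_invariant_under_rot90(self, rng):
        q = rng.integers(1, 5, size=(7, 9))
        a = texture_features(q, n_levels=4)
        b = texture_features(np.rot90(q), n_levels=4)
        for k in a:
            if k.startswith(("glcm_", "glrlm_")):
                assert a[k] == pytest.approx(b[k], abs=1e-9), k


class TestAws:
    def test_symmetric_matrix_gives_su(self):
        P = np.array([[0.2, 0.1, 0.0], [0.1, 0.3, 0.1], [0.0, 0.1, 0.1]])
        su = 0.1 * 1 + 0.1 * 1  # upper triangle weighted by |i-j|
        assert aws_feature(P) == pytest.approx(su)

    def test_diagonal_only_matrix_is_zero(self):
        assert aws_feature(np.diag([0.5, 0.3, 0.2])) == 0.0

    def test_hand_built_asymmetric_matrix(self):
        P = np.array([[0.1, 0.2, 0.1], [0.0, 0.2, 0.1], [0.1, 0.0, 0.2]])
        s_u = 0.2 * 1 + 0.1 * 2 + 0.1 * 1
        s_l = 0.1 * 2
        w = s_u / (s_u + s_l)
        assert aws_feature(P) == pytest.approx(w * s_u + (1 - w) * s_l)
        assert aws_feature(P) == pytest.approx(ref.ref_aws(P))

    def test_zero_iff_diagonal(self, rng):
        for _ in range(20):
            q = rng.integers(1, 4, size=(5, 5))
            m = glcm(q, (0, 1), n_levels=3, symmetric=False)
            off_diag = m.normalized.copy()
            np.fill_diagonal(off_diag, 0.0)
            assert (aws_feature(m) == 0.0) == (off_diag.sum() == 0.0)


class TestShape:
    def test_filled_circle(self):
        n = 101
        rows, cols = np.mgrid[0:n, 0:n]
        mask = np.hypot(rows - 50, cols - 50) <= 40
        f = shape2d_features(mask)
        assert f["shape_area"] == pytest.approx(np.pi * 40 ** 2, rel=0.02)
        assert f["shape_sphericity"] == pytest.approx(1.0, abs=0.1)
        assert f["shape_maximum_diameter"] == pytest.approx(80, abs=2)
        assert f["shape_equivalent_diameter"] == pytest.approx(80, abs=2)

    def test_single_pixel_conventions(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        f = shape2d_features(mask)
        assert f["shape_maximum_diameter"] == 0.0
        assert f["shape_area"] == 1.0

    def test_isoperimetric_ordering(self):
        square = np.zeros((60, 60), bool)
        square[10:46, 10:46] = True          # 36x36 square, area 1296
        n = 101
        rows, cols = np.mgrid[0:n, 0:n]
        circle = np.hypot(rows - 50, cols - 50) <= 20.3  # about the same area
        assert (shape2d_features(square)["shape_sphericity"]
                < shape2d_features(circle)["shape_sphericity"])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape2d_features(np.zeros((4, 4), bool))


class TestVector:
    def test_length_and_names(self, rng):
        roi = rng.integers(0, 256, size=(40, 40)).astype(float)
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        vec = assemble_vector(roi, mask, RECORD)
        assert len(vec) == 89
        assert len(set(vec.names)) == 89
        assert list(vec.names) == FEATURE_NAMES

    def test_age_changes_only_age_entry(self, rng):
        roi = rng.integers(0, 256, size=(30, 30)).astype(float)
        mask = np.ones((30, 30), bool)
        older = PatientRecord(gender="female", smoking="ex-smoker", age=75.0,
                              lesion_size="<3cm", label=0)
        a = assemble_vector(roi, mask, RECORD)
        b = assemble_vector(roi, mask, older)
        diff = np.nonzero(a.values != b.values)[0]
        assert [a.names[i] for i in diff] == ["clinical_age"]

    def test_constant_lesion_has_no_nan(self):
        roi = np.full((40, 40), 128.0)
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        vec = assemble_vector(roi, mask, RECORD)
        assert np.isfinite(vec.values).all()
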