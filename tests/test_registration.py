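"""Field calculus (Jacobian, inversion, resampling) and the three-stage
constrained registration."""

import numpy as np
import pytest

import wbatlas as wb
from wbatlas.grids import DisplacementField, LabelMap, SubjectDataset, VolumeGrid
from wbatlas.registration import RegistrationConfig, register_bones, register_stage


def _const_field(shape, vec, spacing=(4, 4, 4)):
    v = np.zeros(shape + (3,))
    v[...] = vec
    return DisplacementField(v, spacing, (0, 0, 0))


class TestJacobian:
    def test_zero_field_is_identity(self):
        fld = _const_field((8, 8, 8), (0, 0, 0))
        jac = wb.jacobian(fld)
        np.testing.assert_allclose(jac.det.data, 1.0, atol=1e-12)
        np.testing.assert_allclose(jac.log_det.data, 0.0, atol=1e-12)

    def test_any_translation_has_unit_determinant(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            fld = _const_field((6, 7, 8), rng.normal(0, 10, 3))
            np.testing.assert_allclose(wb.jacobian(fld).det.data, 1.0, atol=1e-9)

    def test_uniform_ten_percent_expansion(self):
        # u(x) = 0.1 x  =>  det = 1.1^3 = 1.331 everywhere (exact for linear)
        shape, spacing = (10, 10, 10), np.array([4.0, 4.0, 4.0])
        idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        v = np.stack([0.1 * idx[a] * spacing[a] for a in range(3)], axis=-1)
        jac = wb.jacobian(DisplacementField(v, spacing, (0, 0, 0)))
        np.testing.assert_allclose(jac.det.data, 1.331, atol=1e-9)
        np.testing.assert_allclose(jac.log_det.data, np.log(jac.det.data),
                                   atol=1e-9)

    def test_quadratic_field_matches_symbolic_determinant(self):
        # u = (a x y, b y z, c z x): central differences are exact for
        # quadratics, so the numeric det must match the hand-derived one
        a, b, c = 2e-3, -1.5e-3, 1e-3
        shape, spacing = (12, 11, 10), np.array([4.0, 4.0, 4.0])
        X, Y, Z = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                              indexing="ij")
        v = np.stack([a * X * Y, b * Y * Z, c * Z * X], axis=-1)
        det = wb.jacobian(DisplacementField(v, spacing, (0, 0, 0))).det.data
        # J = I + [[aY, aX, 0], [0, bZ, bY], [cZ, 0, cX]]
        expected = ((1 + a * Y) * (1 + b * Z) * (1 + c * X)
                    + a * X * b * Y * c * Z)
        np.testing.assert_allclose(det[1:-1, 1:-1, 1:-1],
                                   expected[1:-1, 1:-1, 1:-1], atol=1e-3)

    def test_matches_simpleitk_on_smooth_random_field(self):
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(5)
        from wbatlas.grids import smooth_array
        spacing = np.array([4.0, 4.0, 4.0])
        v = np.stack([smooth_array(rng.standard_normal((16, 16, 16)), 3) * 40
                      for _ in range(3)], axis=-1)
        ours = wb.jacobian(DisplacementField(v, spacing, (0, 0, 0))).det.data
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(v.transpose(2, 1, 0, 3)), isVector=True)
        img.SetSpacing(tuple(spacing))
        theirs = sitk.GetArrayFromImage(
            sitk.DisplacementFieldJacobianDeterminant(img)).transpose(2, 1, 0)
        np.testing.assert_allclose(ours[1:-1, 1:-1, 1:-1],
                                   theirs[1:-1, 1:-1, 1:-1], atol=1e-3)


class TestInversion:
    def test_zero_field_inverts_to_zero(self):
        inv, res = wb.invert_field(_const_field((6, 6, 6), (0, 0, 0)))
        assert np.all(inv.vectors == 0)
        assert res.data.max() == 0

    def test_uniform_translation_inverts_to_negation(self):
        t = np.array([6.0, -2.0, 3.0])
        inv, res = wb.invert_field(_const_field((8, 8, 8), t))
        np.testing.assert_allclose(inv.vectors,
                                   np.broadcast_to(-t, inv.vectors.shape),
                                   atol=1e-9)

    def test_synthesis_warp_round_trip_residual(self, coarse_ref_nf):
        spec, _, labels = coarse_ref_nf
        warp = wb.WarpParams(organ_scales={"liver": 1.2}, residual_amp_mm=3.0)
        v = wb.phantom.build_synthesis_map(spec, warp, labels,
                                           np.random.default_rng(1))
        inv, res = wb.invert_field(v)
        body = labels.labels > 0
        assert res.data[body].mean() < 0.2
        assert res.data[body].max() < 1.0


class TestResample:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(2)
        vol = VolumeGrid(rng.standard_normal((7, 7, 7)), (4, 4, 4), (0, 0, 0))
        out = wb.resample(vol, _const_field((7, 7, 7), (0, 0, 0)))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_one_voxel_translation_shifts_exactly(self):
        rng = np.random.default_rng(3)
        vol = VolumeGrid(rng.standard_normal((8, 8, 8)), (4, 4, 4), (0, 0, 0))
        out = wb.resample(vol, _const_field((8, 8, 8), (4, 0, 0)))
        np.testing.assert_allclose(out.data[:-1], vol.data[1:], atol=1e-12)
        np.testing.assert_array_equal(out.data[-1], 0.0)  # out of domain

    def test_out_of_domain_flagged_in_validity_mask(self):
        vol = VolumeGrid(np.ones((6, 6, 6)), (4, 4, 4), (0, 0, 0))
        out, valid = wb.resample(vol, _const_field((6, 6, 6), (4, 0, 0)),
                                 return_valid=True)
        assert valid[:-1].all() and not valid[-1].any()

    def test_label_round_trip_through_field_and_inverse(self, coarse_ref_nf):
        spec, _, labels = coarse_ref_nf
        warp = wb.WarpParams(organ_scales={"liver": 1.15}, residual_amp_mm=2.5)
        v = wb.phantom.build_synthesis_map(spec, warp, labels,
                                           np.random.default_rng(7))
        inv, _ = wb.invert_field(v)
        once = wb.resample_labels(labels, v)
        back = wb.resample_labels(once, inv)
        body = labels.labels > 0
        agreement = np.mean(back.labels[body] == labels.labels[body])
        assert agreement > 0.95

    def test_composition_consistent_with_sequential_resampling(self):
        from wbatlas.grids import smooth_array
        rng = np.random.default_rng(4)
        shape, spacing = (16, 16, 16), (4.0, 4.0, 4.0)
        img = VolumeGrid(smooth_array(rng.standard_normal(shape), 2.5),
                         spacing, (0, 0, 0))
        u1 = _const_field(shape, (4.0, -4.0, 0.0), spacing)
        v2 = np.stack([smooth_array(rng.standard_normal(shape), 3) * 10
                       for _ in range(3)], axis=-1)
        u2 = DisplacementField(v2, spacing, (0, 0, 0))
        seq = wb.resample(wb.resample(img, u1), u2)
        comp = wb.resample(img, wb.compose(u1, u2))
        inner = slice(3, -3)
        np.testing.assert_allclose(comp.data[inner, inner, inner],
                                   seq.data[inner, inner, inner], atol=0.02)


def _toy_bone_setup():
    shape, spacing = (24, 24, 24), (4.0, 4.0, 4.0)
    bones = np.zeros(shape, np.int16)
    bones[4:8, 10:14, 10:14] = 1
    bones[16:20, 10:14, 10:14] = 2
    ref_bones = LabelMap(bones, {1: "seg_a", 2: "seg_b"}, spacing, (0, 0, 0))
    sub_bones_arr = np.zeros(shape, np.int16)
    sub_bones_arr[6:10, 10:14, 10:14] = 1           # seg_a shifted +2 vox in x
    sub_bones_arr[16:20, 9:13, 10:14] = 2           # seg_b shifted -1 vox in y
    sub_bones = LabelMap(sub_bones_arr, {1: "seg_a", 2: "seg_b"}, spacing, (0, 0, 0))
    dummy = VolumeGrid(np.zeros(shape), spacing, (0, 0, 0))
    mk = lambda b: SubjectDataset("t", dummy, dummy, dummy, 75, 150,
                                  native_bones=b)
    return ref_bones, mk(ref_bones), mk(sub_bones)


class TestBones:
    def test_identical_subject_gives_zero_field_on_bones(self):
        ref_bones, ref_sub, _ = _toy_bone_setup()
        fld = register_bones(ref_sub, ref_sub, ref_bones, RegistrationConfig())
        assert np.all(fld.vectors[ref_bones.labels > 0] == 0)

    def test_each_segment_recovers_its_own_shift(self):
        ref_bones, ref_sub, moved = _toy_bone_setup()
        fld = register_bones(moved, ref_sub, ref_bones, RegistrationConfig())
        seg_a = fld.vectors[ref_bones.labels == 1]
        seg_b = fld.vectors[ref_bones.labels == 2]
        np.testing.assert_allclose(
            seg_a, np.broadcast_to([8.0, 0.0, 0.0], seg_a.shape), atol=2.0)
        np.testing.assert_allclose(
            seg_b, np.broadcast_to([0.0, -4.0, 0.0], seg_b.shape), atol=2.0)
        # blend between segments stays bounded by the segment shifts
        assert np.abs(fld.vectors[..., 0]).max() <= 8.0 + 1e-9
        assert np.abs(fld.vectors[..., 1]).max() <= 4.0 + 1e-9


class TestStages:
    def test_null_registration_returns_negligible_field(self, coarse_ref_nf):
        spec, ref, labels = coarse_ref_nf
        init = wb.DisplacementField.zero(ref.fat)
        fld, report = register_stage("water", ref, ref, init, None,
                                     RegistrationConfig())
        assert fld.magnitude_voxels().max() < 0.1
        assert not report["failed"]

    def test_fully_constrained_stage_returns_init_exactly(self, coarse_ref_nf):
        spec, ref, labels = coarse_ref_nf
        recipe = wb.SubjectRecipe("s", seed=6,
                                  warp=wb.WarpParams(translation_mm=(6, 0, 0)),
                                  tissue_jitter=False, noise=False)
        sub, _ = wb.make_subject(spec, recipe, ref)
        init = wb.DisplacementField.zero(ref.fat)
        whole = np.ones(spec.shape, bool)
        fld, _ = register_stage("water", sub, ref, init, whole,
                                RegistrationConfig())
        np.testing.assert_array_equal(fld.vectors, init.vectors)

    def test_identity_subject_full_registration(self, coarse_ref_nf):
        spec, ref, labels = coarse_ref_nf
        recipe = wb.SubjectRecipe("s", seed=7, tissue_jitter=False, noise=False)
        sub, _ = wb.make_subject(spec, recipe, ref)
        fld, jac, report = wb.register_subject(sub, ref, labels)
        body = labels.labels > 0
        np.testing.assert_allclose(jac.det.data[body], 1.0, atol=0.02)
        assert not report["poor_registration"]

    def test_water_regularisation_must_dominate_fat(self):
        with pytest.raises(wb.ParameterError):
            RegistrationConfig(water_field_sigma_mm=2.0, fat_field_sigma_mm=4.0)


class TestFullRecovery:
    def test_known_warp_recovered_within_one_voxel(self, warp_recovery):
        w = warp_recovery
        body = w["labels"].labels > 0
        epe = np.sqrt((((w["est_field"].vectors - w["true_field"].vectors)
                        / w["spec"].spacing) ** 2).sum(-1))
        assert epe[body].mean() < 1.0

    def test_bone_voxels_carry_bone_stage_field_exactly(self, warp_recovery):
        w = warp_recovery
        bone_field = register_bones(w["subject"], w["ref"],
                                    w["ref"].native_bones, RegistrationConfig())
        bones = w["ref"].native_bones.labels > 0
        np.testing.assert_array_equal(w["est_field"].vectors[bones],
                                      bone_field.vectors[bones])

    def test_mse_trajectory_monotone_and_improving(self, warp_recovery):
        t = warp_recovery["report"]["mse_trajectory"]
        assert t["fat"] <= t["water"] <= t["bones"] <= t["initial"]

    def test_registration_conserves_body_volume(self, warp_recovery):
        w = warp_recovery
        body = w["labels"].labels > 0
        est = w["jac"].det.data[body].sum()
        native = (w["subject"].native_labels.labels > 0).sum()
        assert est / native == pytest.approx(1.0, abs=0.03)
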