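import numpy as np
import pytest

from sctqa.core import Geometry, StructureError, VectorField, VolumeGrid
from sctqa.phantom import PhantomParams, generate_patient, _smooth_unit_field
from sctqa.registration import (
    bone_refinement,
    compose,
    demons_stage,
    dice,
    jacobian_positive_fraction,
    qa_gate,
    rigid_translate,
    staged_registration,
    warp,
    warp_mask,
)
from sctqa.structural import build_sd, organ_field


GEO = Geometry((16, 16, 16), (2.0, 2.0, 2.0))


def smooth_volume(seed=0, geo=GEO):
    rng = np.random.default_rng(seed)
    (f,) = _smooth_unit_field(geo.shape, geo.spacing, 10.0, rng)
    return VolumeGrid(f * 50.0 + 100.0, geo.spacing)


def smooth_field(seed=0, amp=3.0, geo=GEO):
    rng = np.random.default_rng(seed)
    fs = _smooth_unit_field(geo.shape, geo.spacing, 14.0, rng, n_channels=3)
    return VectorField(np.stack([amp / np.sqrt(3) * f for f in fs], -1), geo)


class TestWarp:
    def test_zero_field_is_identity(self):
        vol = smooth_volume(1)
        out = warp(vol, VectorField.zeros(GEO))
        np.testing.assert_allclose(out.values, vol.values, atol=1e-12)

    def test_constant_one_voxel_shift(self):
        vol = smooth_volume(2)
        out = warp(vol, VectorField.constant(GEO, (2.0, 0.0, 0.0)))
        np.testing.assert_allclose(out.values[:-1], vol.values[1:], atol=1e-9)

    def test_mask_warp_stays_binary(self):
        rng = np.random.default_rng(3)
        mask = rng.random(GEO.shape) > 0.6
        out = warp_mask(mask, smooth_field(3))
        assert out.dtype == bool


class TestCompose:
    def test_zero_is_identity_element(self):
        f = smooth_field(4)
        z = VectorField.zeros(GEO)
        np.testing.assert_allclose(compose(z, f).displacement,
                                   f.displacement, atol=1e-12)
        np.testing.assert_allclose(compose(f, z).displacement,
                                   f.displacement, atol=1e-12)

    def test_constant_translations_add(self):
        a = VectorField.constant(GEO, (1.0, -2.0, 0.5))
        b = VectorField.constant(GEO, (0.5, 1.0, 1.0))
        out = compose(a, b)
        np.testing.assert_allclose(out.displacement[3, 3, 3],
                                   [1.5, -1.0, 1.5], atol=1e-9)

    def test_double_warp_oracle(self):
        """warp(v, compose(f1, f2)) == warp(warp(v, f1), f2) on smooth data
        within interpolation tolerance."""
        vol = smooth_volume(5)
        f1, f2 = smooth_field(6, amp=2.0), smooth_field(7, amp=2.0)
        once = warp(vol, compose(f1, f2), edge="nearest")
        twice = warp(warp(vol, f1, edge="nearest"), f2, edge="nearest")
        inner = (slice(2, -2),) * 3
        err = np.abs(once.values - twice.values)[inner]
        assert err.max() < 0.05 * np.ptp(vol.values)


class TestDice:
    def test_identical_and_disjoint(self):
        m = np.zeros((10, 10, 10), bool)
        m[:5] = True
        assert dice(m, m) == 1.0
        assert dice(m, ~m) == 0.0

    def test_half_offset_cubes(self):
        a = np.zeros((20, 10, 10), bool)
        b = np.zeros((20, 10, 10), bool)
        a[0:10], b[5:15] = True, True
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_empty_is_vacuous_agreement(self):
        z = np.zeros((4, 4, 4), bool)
        assert dice(z, z) == 1.0


class TestQaGate:
    DICES = {o: 0.9 for o in ("body", "bones", "bladder", "rectum",
                              "prostate")}

    def test_all_pass(self):
        ok, report = qa_gate(self.DICES)
        assert ok and report["passed"] and not report["failures"]

    def test_threshold_is_strict(self):
        d = dict(self.DICES, rectum=0.85)
        ok, report = qa_gate(d)
        assert not ok
        assert "rectum" in report["failures"]

    def test_perfect_scores_pass(self):
        ok, _ = qa_gate({o: 1.0 for o in self.DICES})
        assert ok

    def test_missing_organ_rejected(self):
        with pytest.raises(StructureError):
            qa_gate({"body": 0.9})


@pytest.fixture(scope="module")
def pair(small_params):
    return (generate_patient(small_params, 11),
            generate_patient(small_params, 22))


class TestRigidTranslate:
    def test_identical_images_give_zero(self, case):
        sd = build_sd(case.mri, case.structures)
        f = rigid_translate(sd.organ_merged, sd.organ_merged,
                            case.structures["body"], case.structures["body"])
        assert f.max_magnitude() == 0.0

    def test_known_shift_recovered(self, case):
        """An 8 mm (2 voxel) shift of the phantom is recovered within one
        voxel.  np.roll(v, -k) moves content by -k voxels, so the backward
        translation that re-aligns it is -k * spacing."""
        sd = build_sd(case.mri, case.structures)
        shift_vox = 2
        moved = np.roll(sd.organ_merged.values, -shift_vox, axis=0)
        moved_body = np.roll(case.structures["body"], -shift_vox, axis=0)
        f = rigid_translate(sd.organ_merged.like(moved), sd.organ_merged,
                            moved_body, case.structures["body"])
        t = f.displacement[0, 0, 0]
        assert abs(t[0] - (-shift_vox * 4.0)) <= 4.0
        assert abs(t[1]) <= 4.0 and abs(t[2]) <= 4.0

    def test_recovered_translation_is_a_fixed_point(self, case):
        """Applying the recovered translation and re-estimating gives ~0."""
        sd = build_sd(case.mri, case.structures)
        moved = np.roll(sd.organ_merged.values, -2, axis=0)
        moved_body = np.roll(case.structures["body"], -2, axis=0)
        f = rigid_translate(sd.organ_merged.like(moved), sd.organ_merged,
                            moved_body, case.structures["body"])
        realigned = warp(sd.organ_merged.like(moved), f, edge="nearest")
        realigned_body = warp_mask(moved_body, f)
        f2 = rigid_translate(realigned, sd.organ_merged,
                             realigned_body, case.structures["body"])
        assert f2.max_magnitude() <= 4.0


class TestDemons:
    def test_identity_input_gives_tiny_field(self, case):
        f = organ_field(case.structures["bladder"], case.geometry)
        out = demons_stage(f, f, (50, 50, 20, 5))
        assert out.max_magnitude() < 0.1 * min(case.geometry.spacing)

    def test_zero_schedule_returns_initial(self, case):
        f = organ_field(case.structures["bladder"], case.geometry)
        init = smooth_field(8, amp=2.0, geo=case.geometry)
        out = demons_stage(f, f, (0, 0, 0, 0), initial=init)
        np.testing.assert_array_equal(out.displacement, init.displacement)

    def test_known_smooth_warp_recovered(self):
        """fixed = I o (id + W) with a known smooth W: on an image with
        gradients everywhere the estimated field matches W within one voxel
        mean error (away from the boundary, where W points outside)."""
        geo = Geometry((32, 32, 32), (2.0, 2.0, 2.0))
        img = smooth_volume(9, geo=geo)
        w = smooth_field(10, amp=4.0, geo=geo)
        fixed = warp(img, w, edge="nearest")
        est = demons_stage(fixed, img, (100, 100, 50, 10))
        err = np.sqrt(((est.displacement - w.displacement) ** 2).sum(-1))
        inner = (slice(4, -4),) * 3
        assert err[inner].mean() < min(geo.spacing)

    def test_non_finite_input_rejected(self, case):
        f = organ_field(case.structures["bladder"], case.geometry)
        bad = f.like(f.values.copy())
        bad.values[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            demons_stage(f, bad, (10, 0, 0, 0))


class TestStagedRegistration:
    def test_self_registration_is_identity(self, case):
        res = staged_registration(case, case)
        assert res.field.max_magnitude() < 0.1 * min(case.geometry.spacing)
        for organ, d in res.dices.items():
            assert d == 1.0, organ
        assert res.gate_passed

    def test_phantom_pair_aligns_and_is_diffeomorphic(self, pair):
        case, template = pair
        res = staged_registration(case, template)
        for organ, d in res.dices.items():
            assert d > 0.8, (organ, d)   # coarse 4 mm grid; gate uses 3 mm
        frac = jacobian_positive_fraction(res.field,
                                          template.structures["body"])
        assert frac > 0.99

    def test_composition_consistency(self, case):
        """One-shot mask warp through a composed field agrees with the two
        sequential warps within a one-voxel boundary band."""
        from scipy import ndimage
        geo = case.geometry
        f1 = smooth_field(21, amp=4.0, geo=geo)
        f2 = smooth_field(22, amp=4.0, geo=geo)
        mask = case.structures["bladder"]
        once = warp_mask(mask, compose(f1, f2))
        seq = warp_mask(warp_mask(mask, f1), f2)
        band = (ndimage.binary_dilation(once) & ~ndimage.binary_erosion(once)) \
            | (ndimage.binary_dilation(seq) & ~ndimage.binary_erosion(seq))
        assert ((once ^ seq) & ~band).sum() == 0


class TestBoneRefinement:
    def test_partition_matches_generator_labels(self, case):
        zero = VectorField.zeros(case.geometry)
        _, info = bone_refinement(case.ct, case.structures["bones"],
                                  case.ct, case.structures["bones"], zero)
        assert dice(info["template"]["cortical"],
                    case.structures["cortical"]) >= 0.8
        assert dice(info["template"]["spongy"],
                    case.structures["spongy"]) >= 0.8

    def test_uniform_bones_skip_refinement(self, case):
        flat = case.ct.like(np.where(case.structures["bones"], 300.0,
                                     case.ct.values))
        zero = VectorField.zeros(case.geometry)
        out, info = bone_refinement(flat, case.structures["bones"],
                                    flat, case.structures["bones"], zero)
        assert info == {}
        np.testing.assert_array_equal(out.displacement, zero.displacement)

    def test_refinement_keeps_bones_above_gate(self, pair):
        case, template = pair
        res = staged_registration(case, template)
        ct_ccs = warp(case.ct, res.field)
        bones_ccs = warp_mask(case.structures["bones"], res.field)
        refined, info = bone_refinement(ct_ccs, bones_ccs, template.ct,
                                        template.structures["bones"],
                                        res.field)
        assert info, "refinement unexpectedly skipped"
        before_sp = dice(warp_mask(case.structures["spongy"], res.field),
                         template.structures["spongy"])
        after_sp = dice(warp_mask(case.structures["spongy"], refined),
                        template.structures["spongy"])
        after_bones = dice(warp_mask(case.structures["bones"], refined),
                           template.structures["bones"])
        assert after_sp >= before_sp - 0.01     # spongy alignment not degraded
        assert after_bones > 0.85               # whole bone stays above gate
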