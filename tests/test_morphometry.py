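"""Morphometric operators against analytic phantoms and topology oracles."""

import numpy as np
import pytest

from trabkit.morphometry import (MorphometryConfig, bvtv, euler_connectivity,
                                 local_thickness, mil_fabric, smi, summarize,
                                 tb_n)
from trabkit.phantoms import (PhantomSpec, degrade, make_isotropic_phantom,
                              make_plate_phantom)
from trabkit.segmentation import BinaryVOI, purge
from trabkit.voi import VOIVolume, sphere_mask

from .conftest import as_binary_voi

VOX = 0.02


def _geometry(kind, n=96, radius=15):
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = n // 2
    if kind == "ball":
        return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    if kind == "cylinder":
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    if kind == "slab":
        return np.abs(zz - c) < radius  # thickness 2·radius voxels
    raise ValueError(kind)


class TestBVTV:
    def test_half_filled_sphere(self):
        n = 63
        bone = np.zeros((n, n, n), bool)
        bone[: n // 2 + 1] = True  # half-space through the sphere centre
        b = as_binary_voi(bone, VOX)
        assert bvtv(b) == pytest.approx(0.5, abs=0.02)

    def test_plate_phantom_fraction(self, plate64):
        b, gt = plate64
        assert bvtv(b) == pytest.approx(gt.bvtv, abs=0.025)

    def test_empty_bone_warns(self):
        b = as_binary_voi(np.zeros((33, 33, 33), bool), VOX)
        with pytest.warns(UserWarning):
            assert bvtv(b) == 0.0


class TestLocalThickness:
    def test_slab_thickness(self):
        b = as_binary_voi(_geometry("slab", radius=5), VOX)  # 10 voxels thick
        th, _ = local_thickness(b, "bone")
        assert th == pytest.approx(10 * VOX, abs=VOX)

    def test_cylinder_diameter(self):
        b = as_binary_voi(_geometry("cylinder", n=96, radius=15), VOX)
        th, _ = local_thickness(b, "bone")
        assert th == pytest.approx(0.60, abs=VOX)

    def test_plate_phantom_thickness_and_spacing(self, plate64):
        b, gt = plate64
        assert local_thickness(b, "bone")[0] == pytest.approx(
            gt.tb_th_mm, abs=VOX)
        assert local_thickness(b, "background")[0] == pytest.approx(
            gt.tb_sp_mm, abs=VOX)

    def test_empty_phase_rejected(self):
        b = as_binary_voi(np.zeros((33, 33, 33), bool), VOX)
        with pytest.raises(ValueError, match="empty"):
            local_thickness(b, "bone")


class TestTbN:
    def test_plate_period_small(self):
        # period 0.32 mm → 3.125 trabeculae per mm
        spec = PhantomSpec("plates", (96, 96, 96), VOX,
                          plate_thickness_mm=0.12, plate_spacing_mm=0.2)
        vol, gt = make_plate_phantom(spec)
        b = as_binary_voi(vol.values, VOX)
        assert tb_n(b) == pytest.approx(gt.tb_n_per_mm, rel=0.05)

    def test_plate_model_consistency(self, plate64):
        # |Tb.N − 1/(Tb.Th + Tb.Sp)| / Tb.N ≤ 0.15 on periodic plates
        b, _ = plate64
        n = tb_n(b)
        th = local_thickness(b, "bone")[0]
        sp = local_thickness(b, "background")[0]
        assert abs(n - 1.0 / (th + sp)) / n <= 0.15

    def test_single_blob_warns(self):
        b = as_binary_voi(_geometry("ball", n=64, radius=28), VOX)
        # a solid ball has a single central mid-axis cluster: the spacing
        # estimate must stay finite and positive
        val = tb_n(b)
        assert 0 < val < 10


class TestEulerConnectivity:
    def test_solid_ball_has_no_loops(self, ball96):
        chi, conn = euler_connectivity(ball96)
        assert chi == 1
        assert conn == 0.0

    def test_torus_has_one_loop(self, torus96):
        chi, conn = euler_connectivity(torus96)
        assert chi == 0
        assert conn == pytest.approx(1.0 / torus96.sphere_volume_mm3)

    def test_cubic_frame_euler(self):
        # 8 joints, 12 struts: χ = V − E = −4, so β₁ = 5
        frame = np.zeros((64, 64, 64), bool)
        s, e, w = 12, 52, 4
        for a in (s, e):
            for b_ in (s, e):
                frame[a - w:a + w, b_ - w:b_ + w, s - w:e + w] = True
                frame[a - w:a + w, s - w:e + w, b_ - w:b_ + w] = True
                frame[s - w:e + w, a - w:a + w, b_ - w:b_ + w] = True
        b = BinaryVOI(frame, np.ones_like(frame), VOX, 0.0, frame)
        chi, _ = euler_connectivity(b)
        assert chi == -4

    def test_multi_component_warns(self):
        bone = np.zeros((33, 33, 33), bool)
        bone[10:13, 10:13, 10:13] = True
        bone[20:23, 20:23, 20:23] = True
        with pytest.warns(UserWarning, match="components"):
            euler_connectivity(as_binary_voi(bone, VOX))


class TestSMI:
    def test_sphere_is_four(self, ball96):
        assert smi(ball96) == pytest.approx(4.0, abs=0.3)

    def test_cylinder_is_three(self):
        b = as_binary_voi(_geometry("cylinder", n=96, radius=15), VOX)
        assert smi(b) == pytest.approx(3.0, abs=0.3)

    def test_wide_plate_is_zero(self):
        b = as_binary_voi(_geometry("slab", n=96, radius=6), VOX)
        assert smi(b) == pytest.approx(0.0, abs=0.3)

    def test_invalid_epsilon_rejected(self, ball96):
        with pytest.raises(ValueError):
            smi(ball96, dilation_eps_mm=-1.0)
        with pytest.raises(ValueError):
            smi(ball96, dilation_eps_mm=10 * ball96.voxel_mm)


class TestMILFabric:
    def test_isotropic_phantom_da_near_one(self):
        spec = PhantomSpec("isotropic", (96, 96, 96), 0.03, target_bvtv=0.3,
                          correlation_length_mm=0.3, seed=2)
        vol, _ = make_isotropic_phantom(spec)
        fab = mil_fabric(as_binary_voi(vol.values, 0.03), 128, seed=0)
        assert 1.0 <= fab.da <= 1.15

    def test_plate_phantom_anisotropy_and_axis(self, plate64):
        b, gt = plate64
        fab = mil_fabric(b, 128, seed=0)
        assert fab.da > 2.0
        # smallest-MIL direction is the plate normal (z)
        angle = np.degrees(np.arccos(min(1.0, abs(fab.minor_axis[2]))))
        assert angle < 5.0

    def test_da_at_least_one_by_construction(self):
        spec = PhantomSpec("isotropic", (64, 64, 64), 0.03, target_bvtv=0.4,
                          correlation_length_mm=0.25, seed=7)
        vol, _ = make_isotropic_phantom(spec)
        fab = mil_fabric(as_binary_voi(vol.values, 0.03), 64, seed=3)
        assert fab.da >= 1.0
        assert fab.mil[0] >= fab.mil[1] >= fab.mil[2]

    def test_single_phase_rejected(self):
        b = as_binary_voi(np.ones((48, 48, 48), bool), VOX)
        with pytest.raises(ValueError, match="both phases"):
            mil_fabric(b, 64)


class TestScaleAndRotationInvariance:
    def test_voxel_size_equivariance(self, plate64):
        b, _ = plate64
        doubled = BinaryVOI(b.bone, b.mask, 2 * b.voxel_mm, 0.0, b.bone_cube)
        assert local_thickness(doubled, "bone")[0] == pytest.approx(
            2 * local_thickness(b, "bone")[0])
        assert tb_n(doubled) == pytest.approx(tb_n(b) / 2)
        assert bvtv(doubled) == bvtv(b)
        _, cd = euler_connectivity(purge(doubled))
        _, cd0 = euler_connectivity(purge(b))
        assert cd == pytest.approx(cd0 / 8)
        assert smi(doubled, smooth_sigma=1.0) == pytest.approx(
            smi(b, smooth_sigma=1.0), abs=1e-9)

    def test_axis_rotation_leaves_scalars_unchanged(self, torus96):
        rot = np.transpose(torus96.bone_cube, (1, 2, 0)).copy()
        b_rot = as_binary_voi(rot, torus96.voxel_mm)
        assert bvtv(b_rot) == pytest.approx(bvtv(torus96))
        assert euler_connectivity(b_rot)[0] == euler_connectivity(torus96)[0]
        assert local_thickness(b_rot, "bone")[0] == pytest.approx(
            local_thickness(torus96, "bone")[0])
        # marching-cubes triangulation is not bitwise symmetric under axis
        # permutation; the surface integrals agree to discretization noise
        assert smi(b_rot) == pytest.approx(smi(torus96), abs=0.01)


class TestSummarize:
    @pytest.fixture(scope="class")
    def plate_voi(self):
        spec = PhantomSpec("plates", (64, 64, 64), VOX,
                          plate_thickness_mm=0.2, plate_spacing_mm=0.44)
        vol, gt = make_plate_phantom(spec)
        gray = degrade(vol, 0.0, 5.0, seed=1)
        n = 63
        voi = VOIVolume(np.ascontiguousarray(gray.values[:n, :n, :n]),
                        sphere_mask(n), VOX)
        return voi, gt

    def test_end_to_end_plate_recovery(self, plate_voi):
        voi, gt = plate_voi
        s = summarize(voi, MorphometryConfig(seed=0))
        assert s.bvtv == pytest.approx(gt.bvtv, abs=0.03)
        assert s.tb_th_mm == pytest.approx(gt.tb_th_mm, abs=VOX)
        assert s.tb_sp_mm == pytest.approx(gt.tb_sp_mm, abs=VOX)
        assert s.smi == pytest.approx(0.0, abs=0.3)
        assert s.da > 2.0
        assert s.conn_d_per_mm3 == 0.0  # parallel plates have no loops
        # the correction multiplies Tb.Th by the default linear factor
        assert s.tb_th_corr_mm == pytest.approx(
            s.tb_th_mm * (-4.4856 * VOX + 1.0805))
        assert 60.0 < s.threshold < 190.0

    def test_repeat_run_is_identical(self, plate_voi):
        voi, _ = plate_voi
        a = summarize(voi, MorphometryConfig(seed=5))
        b = summarize(voi, MorphometryConfig(seed=5))
        assert a.to_dict() == b.to_dict()

    def test_failing_stages_yield_nans_with_error_log(self):
        # a VOI that is bone except one voxel: the MIL stage cannot find
        # interface crossings and must fail into NaN, recorded in provenance
        n = 33
        vals = np.full((n, n, n), 190.0)
        vals[16, 16, 16] = 100.0
        voi = VOIVolume(vals, sphere_mask(n), VOX)
        s = summarize(voi, MorphometryConfig(seed=0))
        assert s.bvtv > 0.99
        assert np.isnan(s.da)
        assert "da" in s.provenance["errors"]
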