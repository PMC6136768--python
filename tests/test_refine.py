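import warnings

import numpy as np
import pytest
from scipy import ndimage

from carmtomo import (
    DetectorSpec,
    GeometryPerturbation,
    SurfaceMask,
    Volume,
    make_circular_trajectory,
    make_digital_sample,
    perturb_trajectory,
    project_mask,
    refine_scan,
    refine_view,
    register_2d,
    register_mask_3d,
    simulate_scan,
)
from carmtomo.projector import SystemOperator
from carmtomo.refine import (
    ViewCorrection,
    apply_transform_to_mask,
    refined_offsets,
)


@pytest.fixture(scope="module")
def sample64():
    return make_digital_sample("ellipsoid-limb", size=64, voxel_size=1.5,
                               seed=1)


@pytest.fixture(scope="module")
def refine_setup(sample64):
    det = DetectorSpec(160, 160, 2.0)
    traj = make_circular_trajectory(15, 120.0, 1000.0, 500.0, det)
    return det, traj


class TestRegisterMask3D:
    def test_mask_vs_itself_is_identity(self, sample64):
        m = sample64.support
        vol = Volume(m.data.astype(np.float32), m.voxel_size,
                     m.origin.copy())
        tr = register_mask_3d(m, vol)
        assert np.all(np.abs(tr.angles) < 0.1)
        assert np.all(np.abs(tr.translation) < 0.1 * m.voxel_size)

    def test_known_shift_recovered(self, sample64):
        import SimpleITK as sitk

        m = sample64.support
        vol = Volume(m.data.astype(np.float32), m.voxel_size,
                     m.origin.copy())
        shift_vox = np.array([5.0, -3.0, 2.0])
        shift_mm = shift_vox * m.voxel_size
        img = sitk.GetImageFromArray(vol.data.transpose(2, 1, 0))
        img.SetSpacing((m.voxel_size,) * 3)
        img.SetOrigin(tuple(vol.origin))
        t = sitk.TranslationTransform(3, tuple(-shift_mm))
        moved = sitk.Resample(img, img, t, sitk.sitkLinear, 0.0)
        vol_moved = Volume(
            sitk.GetArrayFromImage(moved).transpose(2, 1, 0),
            m.voxel_size, vol.origin.copy(),
        )
        tr = register_mask_3d(m, vol_moved)
        # resampling transforms map output to input: expect -shift
        assert np.allclose(tr.translation, -shift_mm,
                           atol=0.5 * m.voxel_size)
        # and resampling the mask through it reproduces the moved volume
        re = apply_transform_to_mask(m, tr, vol_moved)
        overlap = np.sum(re.data & (vol_moved.data > 0.5)) / np.sum(
            vol_moved.data > 0.5
        )
        assert overlap > 0.95

    def test_known_rotation_recovered(self, sample64):
        import SimpleITK as sitk

        m = sample64.support
        vol = Volume(m.data.astype(np.float32), m.voxel_size,
                     m.origin.copy())
        img = sitk.GetImageFromArray(vol.data.transpose(2, 1, 0))
        img.SetSpacing((m.voxel_size,) * 3)
        img.SetOrigin(tuple(vol.origin))
        rot = sitk.Euler3DTransform()
        rot.SetCenter((0.0, 0.0, 0.0))
        rot.SetRotation(0.0, 0.0, np.deg2rad(-10.0))
        moved = sitk.Resample(img, img, rot, sitk.sitkLinear, 0.0)
        vol_rot = Volume(
            sitk.GetArrayFromImage(moved).transpose(2, 1, 0),
            m.voxel_size, vol.origin.copy(),
        )
        tr = register_mask_3d(m, vol_rot)
        assert tr.angles[2] == pytest.approx(-10.0, abs=0.5)


class TestProjectMask:
    def test_spherical_mask_gives_circular_silhouettes(self, refine_setup):
        det, traj = refine_setup
        n = 48
        x, y, z = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3,
                              indexing="ij")
        sphere = SurfaceMask((x**2 + y**2 + z**2) <= 12**2, 1.5)
        sil = project_mask(sphere, traj)
        for img in sil.data[::5]:
            ys, xs = np.nonzero(img)
            height = ys.max() - ys.min()
            width = xs.max() - xs.min()
            assert abs(height - width) <= 2  # circular to pixel tolerance

    def test_silhouette_area_scales_with_magnification_squared(self):
        det = DetectorSpec(200, 200, 1.0)
        traj = make_circular_trajectory(2, 10.0, 1000.0, 500.0, det)
        n = 32
        x, y, z = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3,
                              indexing="ij")
        ball = (x**2 + y**2 + z**2) <= 8**2
        # same ball, shifted towards the source (smaller SOD = bigger mag)
        m_center = SurfaceMask(ball, 1.0)
        m_closer = SurfaceMask(ball, 1.0,
                               origin=np.array([100.0, 0, 0])
                               - (n - 1) / 2.0)
        a0 = project_mask(m_center, traj).data[0].sum()
        a1 = project_mask(m_closer, traj).data[0].sum()
        mag_ratio = (1000.0 / 400.0) / (1000.0 / 500.0)
        assert a1 / a0 == pytest.approx(mag_ratio**2, rel=0.05)

    def test_empty_mask_rejected(self, refine_setup):
        det, traj = refine_setup
        with pytest.raises(ValueError):
            project_mask(SurfaceMask(np.zeros((8, 8, 8), bool), 1.0), traj)


@pytest.fixture(scope="module")
def projection_pair(sample64, refine_setup):
    det, traj = refine_setup
    data = simulate_scan(sample64.volume, traj)
    op = SystemOperator(traj, sample64.support.shape,
                        sample64.support.voxel_size,
                        sample64.support.origin)
    thick = op.forward(sample64.support.data.astype(np.float32))
    return det, data.data[3], thick.data[3]


class TestRegister2D:
    def test_identical_images_give_zero_correction(self, projection_pair):
        det, img, thick = projection_pair
        corr = register_2d(thick, img, det)
        assert abs(corr.dh_center) < 0.2
        assert abs(corr.dv_center) < 0.2
        assert abs(corr.ds_reg) < 0.1

    def test_known_shift_recovered(self, projection_pair):
        det, img, thick = projection_pair
        shifted = np.roll(np.roll(img, -6, axis=0), 4, axis=1)
        corr = register_2d(thick, shifted, det)
        assert corr.dh_center == pytest.approx(4.0, abs=0.3)
        assert corr.dv_center == pytest.approx(-6.0, abs=0.3)

    def test_known_rotation_recovered(self, projection_pair):
        det, img, thick = projection_pair
        rotated = ndimage.rotate(img, -2.0, reshape=False, order=3)
        corr = register_2d(thick, rotated, det)
        assert corr.ds_reg == pytest.approx(2.0, abs=0.1)

    def test_blank_data_returns_zero_correction(self, projection_pair):
        det, _, thick = projection_pair
        corr = register_2d(thick, np.zeros_like(thick), det)
        assert corr.dh_reg == corr.dv_reg == corr.ds_reg == 0.0


class TestRefinedOffsets:
    def test_zero_correction_is_identity(self):
        corr = ViewCorrection(0.0, 0.0, 0.0)
        assert refined_offsets(3.0, -4.0, 1.5, corr, 10.0, 20.0) == (
            3.0, -4.0, 1.5
        )

    def test_pure_translation_update(self):
        corr = ViewCorrection(3.0, 0.0, 0.0)
        h, v, s = refined_offsets(1.0, 2.0, 0.5, corr, 10.0, 20.0)
        assert (h, v, s) == (4.0, 2.0, 0.5)

    def test_hand_evaluated_90_degree_case(self):
        """O_h=10, O_v=20, dS=90 degrees, H=V=dH=dV=0:
        H_corr = 0 + 0 + 10 - (10*0 - 20*1) = 30
        V_corr = 0 + 0 + 20 - (10*1 + 20*0) = 10
        """
        corr = ViewCorrection(0.0, 0.0, 90.0)
        h, v, s = refined_offsets(0.0, 0.0, 0.0, corr, 10.0, 20.0)
        assert h == pytest.approx(30.0, abs=1e-12)
        assert v == pytest.approx(10.0, abs=1e-12)
        assert s == pytest.approx(-90.0, abs=1e-12)

    def test_inverse_correction_restores_geometry(self, refine_setup):
        """Applying the exact inverse of a known perturbation restores the
        original offsets and skew (to rounding)."""
        det, traj = refine_setup
        dh, dv, ds = 4.0, -7.0, 1.5
        pert = GeometryPerturbation([dh], [dv], [ds])
        g0 = traj.views[3]
        g_p = perturb_trajectory(traj, GeometryPerturbation(
            dh * np.eye(15)[3], dv * np.eye(15)[3], ds * np.eye(15)[3]
        )).views[3]
        # the registration of a stale mask projection against data acquired
        # with the ORIGINAL geometry measures exactly (+dh, +dv, +ds)
        corr = ViewCorrection.from_center_transform(dh, dv, ds, det)
        g_back = refine_view(g_p, corr, det)
        assert g_back.offset_h == pytest.approx(g0.offset_h, abs=1e-9)
        assert g_back.offset_v == pytest.approx(g0.offset_v, abs=1e-9)
        assert g_back.skew == pytest.approx(g0.skew, abs=1e-9)


class TestRefineScan:
    @pytest.fixture(scope="class")
    def perturbed(self, sample64, refine_setup):
        det, traj = refine_setup
        pert = GeometryPerturbation.random(15, dh_max=10.0, dv_max=10.0,
                                           ds_max=3.0, seed=5)
        traj_true = perturb_trajectory(traj, pert)
        data = simulate_scan(sample64.volume, traj_true)
        return det, traj, traj_true, data

    def test_unperturbed_scan_needs_no_correction(self, sample64,
                                                  refine_setup):
        det, traj = refine_setup
        data = simulate_scan(sample64.volume, traj)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined, report = refine_scan(data, sample64.support, traj,
                                          register_3d=False)
        for r in report:
            assert np.hypot(r["dh"], r["dv"]) < 0.3
            assert abs(r["ds"]) < 0.1

    def test_injected_perturbations_recovered(self, sample64, perturbed):
        det, traj, traj_true, data = perturbed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined, _ = refine_scan(data, sample64.support, traj,
                                     register_3d=False)
        for g_r, g_t in zip(refined.views, traj_true.views):
            assert g_r.offset_h == pytest.approx(g_t.offset_h, abs=0.5)
            assert g_r.offset_v == pytest.approx(g_t.offset_v, abs=0.5)
            assert g_r.skew == pytest.approx(g_t.skew, abs=0.2)

    def test_refinement_improves_fdk(self, sample64, perturbed):
        """The simulated twin of the two-calibrations experiment: FDK with
        stale geometry is visibly degraded; refinement must strictly lower
        the reconstruction RMSE."""
        from carmtomo import fdk_reconstruct

        det, traj, traj_true, data = perturbed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined, _ = refine_scan(data, sample64.support, traj,
                                     register_3d=False)
        vol = sample64.volume
        shape, vs = vol.shape, vol.voxel_size
        rec_stale = fdk_reconstruct(data, shape, vs, trajectory=traj)
        rec_ref = fdk_reconstruct(data, shape, vs, trajectory=refined)
        rmse_stale = np.sqrt(np.mean((rec_stale.data - vol.data) ** 2))
        rmse_ref = np.sqrt(np.mean((rec_ref.data - vol.data) ** 2))
        assert rmse_ref < rmse_stale
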