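"""Adaptive per-acquisition refinement of the geometric calibration.

A hand-moved C-arm does not reproduce its source/detector poses between
rotations, so a periodic phantom calibration is systematically stale by the
time the patient is scanned.  This module refines the three detector-plane
parameters (horizontal offset H, vertical offset V, skew S) for the
*current* acquisition using the patient's surface mask:

1. a preliminary FDK reconstruction from the stale calibration,
2. 3-D rigid mutual-information registration of the surface mask to it,
3. forward projection of the registered mask with the stale calibration,
4. per-view 2-D rigid registration between the mask silhouette and the
   body contour of the measured projection,
5. the closed-form update of H, V, S from the registration parameters.

Errors in the remaining geometric parameters (SDD, pitch, roll) are
deliberately left untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.optimize import minimize
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .containers import ProjectionSet, SurfaceMask, Volume
from .geometry import DetectorSpec, Trajectory, ViewGeometry, make_view_geometry
from .projector import SystemOperator
from .recon import fdk_reconstruct

__all__ = [
    "RigidTransform3D",
    "ViewCorrection",
    "register_mask_3d",
    "project_mask",
    "register_2d",
    "refined_offsets",
    "refine_view",
    "refine_scan",
]


# ---------------------------------------------------------------------------
# 3-D rigid registration (mutual information)
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform3D:
    """Rigid transform: Euler ZYX angles (degrees) plus translation (mm)."""

    angles: np.ndarray  # (3,) degrees, (rx, ry, rz)
    translation: np.ndarray  # (3,) mm
    score: float = float("nan")  # final metric value

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetRotation(*np.deg2rad(self.angles))
        t.SetTranslation(tuple(self.translation))
        return t

    def inverse(self) -> "RigidTransform3D":
        inv = self.to_sitk().GetInverse()
        ang = np.rad2deg(
            [inv.GetAngleX(), inv.GetAngleY(), inv.GetAngleZ()]
        )
        return RigidTransform3D(ang, np.array(inv.GetTranslation()))


def _as_euler(t) -> "sitk.Euler3DTransform":
    if isinstance(t, sitk.Euler3DTransform):
        return t
    comp = sitk.CompositeTransform(t)
    comp.FlattenTransform()
    return sitk.Euler3DTransform(comp.GetNthTransform(0))


def _vol_to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.data.astype(np.float32).transpose(2, 1, 0))
    )
    img.SetSpacing((vol.voxel_size,) * 3)
    img.SetOrigin(tuple(vol.origin))
    return img


def _sitk_to_array(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def register_mask_3d(
    mask: SurfaceMask,
    reco_pre: Volume,
    shrink_factors=(4, 2, 1),
    smoothing_sigmas=(2.0, 1.0, 0.0),
    n_bins: int = 100,
) -> RigidTransform3D:
    """Rigid MI registration of the surface mask onto a reconstruction.

    Mattes mutual information, multi-resolution, gradient-free (Powell)
    optimization with dense sampling — fully deterministic for given
    settings.  Returns the transform that maps mask coordinates into the
    reconstruction frame.
    """
    fixed = _vol_to_sitk(reco_pre)
    moving = _vol_to_sitk(
        Volume(mask.data.astype(np.float32), mask.voxel_size, mask.origin)
    )
    # a light blur turns the binary mask (piecewise-flat MI surface) into
    # a smooth gradient the optimizer can follow to sub-voxel precision
    fixed = sitk.SmoothingRecursiveGaussian(fixed, mask.voxel_size)
    moving = sitk.SmoothingRecursiveGaussian(moving, mask.voxel_size)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=n_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsPowell(
        numberOfIterations=60, maximumLineIterations=40,
        stepLength=1.0, stepTolerance=1e-6, valueTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    final = reg.Execute(fixed, moving)
    e1 = _as_euler(final)
    # fine polish at full resolution with a small step
    reg2 = sitk.ImageRegistrationMethod()
    reg2.SetMetricAsMattesMutualInformation(numberOfHistogramBins=n_bins)
    reg2.SetMetricSamplingStrategy(reg2.NONE)
    reg2.SetInterpolator(sitk.sitkLinear)
    reg2.SetOptimizerAsPowell(
        numberOfIterations=20, maximumLineIterations=30,
        stepLength=0.1, stepTolerance=1e-7, valueTolerance=1e-9,
    )
    reg2.SetOptimizerScalesFromPhysicalShift()
    reg2.SetShrinkFactorsPerLevel([1])
    reg2.SetSmoothingSigmasPerLevel([0.0])
    reg2.SetInitialTransform(e1, inPlace=False)
    final = reg2.Execute(fixed, moving)
    reg = reg2
    e = _as_euler(final)
    ang = np.rad2deg([e.GetAngleX(), e.GetAngleY(), e.GetAngleZ()])
    out = RigidTransform3D(
        ang, np.array(e.GetTranslation()),
        score=float(reg.GetMetricValue()),
    )
    out._center = np.array(e.GetCenter())  # keep the rotation centre
    return out


def apply_transform_to_mask(
    mask: SurfaceMask, transform: RigidTransform3D, reference: Volume
) -> SurfaceMask:
    """Resample the mask through the transform onto the reference grid."""
    t = transform.to_sitk()
    if hasattr(transform, "_center"):
        t.SetCenter(tuple(transform._center))
    moving = _vol_to_sitk(
        Volume(mask.data.astype(np.float32), mask.voxel_size, mask.origin)
    )
    ref = _vol_to_sitk(reference)
    res = sitk.Resample(moving, ref, t, sitk.sitkNearestNeighbor, 0.0)
    return SurfaceMask(
        _sitk_to_array(res) > 0.5, reference.voxel_size,
        reference.origin.copy(),
    )


# ---------------------------------------------------------------------------
# mask projection and per-view 2-D registration
# ---------------------------------------------------------------------------

def project_mask(mask: SurfaceMask, traj: Trajectory) -> ProjectionSet:
    """Binary silhouettes of the mask under the current calibration."""
    if not mask.data.any():
        raise ValueError("empty surface mask")
    op = SystemOperator(traj, mask.shape, mask.voxel_size, mask.origin)
    proj = op.forward(mask.data.astype(np.float32))
    sil = proj.data > 0.5 * mask.voxel_size  # > 0 up to interpolation dust
    return ProjectionSet(
        sil.astype(np.uint8), traj, {"content": "mask_silhouette"}
    )


@dataclass
class ViewCorrection:
    """Per-view 2-D registration result in the update convention of
    :func:`refined_offsets` (rotation referenced to the pixel origin).

    ``dh_center``/``dv_center``/``ds`` keep the raw registration transform
    (translation about the detector centre, rotation degrees) for
    reporting.
    """

    dh_reg: float  # px
    dv_reg: float  # px
    ds_reg: float  # degrees
    dh_center: float = 0.0
    dv_center: float = 0.0
    score_before: float = float("nan")
    score_after: float = float("nan")

    @classmethod
    def from_center_transform(
        cls, t_h: float, t_v: float, ds: float, detector: DetectorSpec,
        score_before=float("nan"), score_after=float("nan"),
    ) -> "ViewCorrection":
        c = np.cos(np.radians(ds))
        s = np.sin(np.radians(ds))
        o_h, o_v = detector.center_h, detector.center_v
        return cls(
            dh_reg=t_h - o_h + (o_h * c - o_v * s),
            dv_reg=t_v - o_v + (o_h * s + o_v * c),
            ds_reg=ds,
            dh_center=t_h,
            dv_center=t_v,
            score_before=score_before,
            score_after=score_after,
        )


def _silhouette(img: np.ndarray) -> np.ndarray:
    """Body silhouette of a projection: Otsu threshold, largest component."""
    img = np.asarray(img, dtype=float)
    if img.max() <= img.min():
        raise ValueError("blank projection")
    binary = img > threshold_otsu(img)
    lab, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no foreground found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def _signed_distance(binary: np.ndarray) -> np.ndarray:
    inside = ndimage.distance_transform_edt(binary)
    outside = ndimage.distance_transform_edt(~binary)
    return outside - inside


def register_2d(
    mask_proj: np.ndarray,
    data: np.ndarray,
    detector: DetectorSpec | None = None,
    max_shift: float = 40.0,
    max_rot: float = 6.0,
) -> ViewCorrection:
    """Rigid 2-D registration of the mask silhouette to the body contour.

    The silhouettes are compared through their signed distance fields
    (a smooth, sub-pixel variant of contour chamfer matching): the cost is
    the mean squared difference of the data field sampled at the
    transformed mask-contour band.  Translation is initialized by phase
    correlation; Nelder-Mead refines (dh, dv, ds) with rotation about the
    detector centre.
    """
    mask_proj = np.asarray(mask_proj)
    if not (mask_proj > 0).any():
        raise ValueError("empty mask silhouette")
    try:
        d_sil = _silhouette(data)
    except ValueError:
        return ViewCorrection(0.0, 0.0, 0.0)  # contour failure: no update
    if mask_proj.dtype.kind == "b" or mask_proj.max() <= 1:
        ref = _signed_distance(np.asarray(mask_proj) > 0)
        tgt = _signed_distance(d_sil)
    else:
        # float thickness image vs measured projection: the two are
        # proportional inside soft tissue, so normalized correlation on
        # the raw images is smooth, sub-pixel and uses interior structure
        ref = mask_proj.astype(float)
        tgt = np.asarray(data, dtype=float)
    if detector is None:
        o_v, o_h = (np.array(d_sil.shape) - 1) / 2.0
    else:
        o_h, o_v = detector.center_h, detector.center_v
    # evaluate over a band around the body contour: the interior is
    # excluded because bone structure is not proportional to thickness and
    # its mismatch would bias the pose estimate
    region = ndimage.binary_dilation(d_sil, iterations=4)
    region &= ~ndimage.binary_erosion(d_sil, iterations=4)
    pv, ph = np.nonzero(region)
    tvals = tgt[pv, ph]
    tvals = tvals - tvals.mean()
    tnorm = np.linalg.norm(tvals) + 1e-12
    shift, _, _ = phase_cross_correlation(
        d_sil.astype(float), (ref > ref.mean()).astype(float)
        if ref.min() < 0 else (ref > 0).astype(float),
        upsample_factor=16, normalization=None,
    )
    t0 = np.array([shift[1], shift[0], 0.0])  # (dh, dv, ds)

    def cost(x):
        dh, dv, ds = x
        if abs(dh) > max_shift or abs(dv) > max_shift or abs(ds) > max_rot:
            return 1e6 + dh * dh + dv * dv + ds * ds
        c = np.cos(np.radians(ds))
        s = np.sin(np.radians(ds))
        # inverse warp: sample the reference at T^-1(x)
        hh = c * (ph - o_h - dh) + s * (pv - o_v - dv) + o_h
        vv = -s * (ph - o_h - dh) + c * (pv - o_v - dv) + o_v
        vals = ndimage.map_coordinates(
            ref, np.vstack([vv, hh]), order=1, mode="nearest"
        )
        vals = vals - vals.mean()
        denom = np.linalg.norm(vals) * tnorm
        if denom <= 0:
            return 1.0
        return 1.0 - float(vals @ tvals) / denom

    score0 = cost([0.0, 0.0, 0.0])
    best = None
    for x0 in (t0, np.array([0.0, 0.0, 0.0])):
        res = minimize(
            cost, x0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-12, "maxfev": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    dh, dv, ds = best.x
    det = detector or DetectorSpec(m.shape[1], m.shape[0], 1.0)
    return ViewCorrection.from_center_transform(
        float(dh), float(dv), float(ds), det,
        score_before=score0, score_after=float(best.fun),
    )


# ---------------------------------------------------------------------------
# the closed-form update
# ---------------------------------------------------------------------------

def refined_offsets(
    h: float, v: float, s: float, corr: ViewCorrection,
    o_h: float, o_v: float,
) -> tuple[float, float, float]:
    """Refined (H, V, S) from the 2-D registration parameters::

        H_corr = H + dH + O_h - (O_h cos(dS) - O_v sin(dS))
        V_corr = V + dV + O_v - (O_h sin(dS) + O_v cos(dS))
        S_corr = S - dS

    ``H``/``V`` are the piercing-point offsets from the detector centre in
    pixels, ``S`` the skew in degrees, ``(O_h, O_v)`` the detector centre.
    """
    c = np.cos(np.radians(corr.ds_reg))
    sn = np.sin(np.radians(corr.ds_reg))
    h_corr = h + corr.dh_reg + o_h - (o_h * c - o_v * sn)
    v_corr = v + corr.dv_reg + o_v - (o_h * sn + o_v * c)
    s_corr = s - corr.ds_reg
    return float(h_corr), float(v_corr), float(s_corr)


def refine_view(
    geom: ViewGeometry, corr: ViewCorrection, detector: DetectorSpec
) -> ViewGeometry:
    """Apply a per-view correction; all other parameters are unchanged.

    The geometry's pixel offsets are detector-shift conventions (piercing
    pixel = centre - offset), so H = -offset.
    """
    h, v, s = -geom.offset_h, -geom.offset_v, geom.skew
    h_corr, v_corr, s_corr = refined_offsets(
        h, v, s, corr, detector.center_h, detector.center_v
    )
    sod = float(np.linalg.norm(geom.source_pos))
    return make_view_geometry(
        geom.angle, geom.sdd, sod, detector,
        skew=s_corr, pitch=geom.pitch, roll=geom.roll,
        offset_h=-h_corr, offset_v=-v_corr,
    )


def refine_scan(
    data: ProjectionSet,
    mask: SurfaceMask,
    geom_ini: Trajectory,
    register_3d: bool = True,
    second_pass_threshold: float | None = None,
) -> tuple[Trajectory, list[dict]]:
    """Full adaptive refinement: preliminary FDK, 3-D mask registration,
    per-view silhouette registration and the H/V/S update.

    Returns the refined trajectory and a per-view correction report.  With
    ``second_pass_threshold`` set, a second refinement round (re-reconstruct
    and re-register) runs when the mean residual correction exceeds it.
    """
    det = data.detector
    try:
        reco_pre = fdk_reconstruct(
            data, mask.shape, mask.voxel_size, mask.origin,
            trajectory=geom_ini,
        )
    except Exception as exc:
        raise RuntimeError(f"preliminary FDK reconstruction failed: {exc}")
    if register_3d:
        t3d = register_mask_3d(mask, reco_pre)
        mask_reg = apply_transform_to_mask(mask, t3d, reco_pre)
        if not mask_reg.data.any():
            warnings.warn("3-D registration moved the mask out of the FOV; "
                          "using the unregistered mask")
            mask_reg = mask
    else:
        mask_reg = mask
    op = SystemOperator(
        geom_ini, mask_reg.shape, mask_reg.voxel_size, mask_reg.origin
    )
    sil = op.forward(mask_reg.data.astype(np.float32))  # float thickness
    out_views, report = [], []
    for i, g in enumerate(geom_ini):
        corr = register_2d(sil.data[i], data.data[i], det)
        g_new = refine_view(g, corr, det)
        out_views.append(g_new)
        report.append(
            {
                "view": i,
                "angle": g.angle,
                "dh": corr.dh_center,
                "dv": corr.dv_center,
                "ds": corr.ds_reg,
                "score_before": corr.score_before,
                "score_after": corr.score_after,
            }
        )
    refined = Trajectory(out_views, det, geom_ini.angular_span)
    if second_pass_threshold is not None:
        mean_res = float(
            np.mean([np.hypot(r["dh"], r["dv"]) for r in report])
        )
        if mean_res > second_pass_threshold:
            refined, report2 = refine_scan(
                data, mask, refined,
                register_3d=register_3d, second_pass_threshold=None,
            )
            report = report + report2
    return refined, report
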