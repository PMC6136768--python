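"""Digital phantoms and projection simulation.

Everything downstream (calibration, refinement, reconstruction, metrics) is
exercised against data produced here: a two-ring ball-bearing calibration
phantom, simple anatomical-like test objects with exact support masks,
cone-beam scans with optional Poisson noise, and the image-intensifier
distortion model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import ProjectionSet, SurfaceMask, Volume
from .geometry import (
    DetectorSpec,
    Trajectory,
    ViewGeometry,
    project_points,
)
from .projector import SystemOperator

__all__ = [
    "CalibPhantomSpec",
    "CalibProjection",
    "DigitalSample",
    "IntensifierDistortion",
    "simulate_calib_projection",
    "simulate_calib_scan",
    "make_digital_sample",
    "simulate_scan",
    "apply_intensifier_distortion",
    "correct_intensifier_distortion",
    "voxelize_mesh",
]


@dataclass(frozen=True)
class CalibPhantomSpec:
    """Two-ring ball-bearing (BB) calibration phantom.

    Eight 0.8 mm steel beads per ring sit equiangularly on two circles of
    diameter ``ring_diameter`` (2R) separated by ``ring_separation`` (H)
    along the cylinder axis, embedded in the wall of a PMMA cylinder.
    ``phase_deg`` is the mounting azimuth of bead 0; the default (11.25°,
    half the bead spacing) keeps projected beads maximally separated at the
    cardinal view angles.
    """

    ring_diameter: float = 49.1  # 2R, mm
    ring_separation: float = 35.0  # H, mm
    beads_per_ring: int = 8
    bead_diameter: float = 0.8  # mm
    cyl_inner_diameter: float = 45.5  # mm
    cyl_outer_diameter: float = 49.5  # mm
    bead_attenuation: float = 8.0  # 1/mm (steel, dominant contrast)
    wall_attenuation: float = 0.02  # 1/mm (PMMA)
    phase_deg: float = 11.25

    def __post_init__(self):
        if self.ring_diameter <= 0 or self.ring_separation <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.beads_per_ring < 1:
            raise ValueError("need at least one bead per ring")

    @property
    def radius(self) -> float:
        return self.ring_diameter / 2.0

    def bead_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of the bead centres, (upper, lower) rings.

        The upper ring sits at z = +H/2, the lower at z = -H/2; beads are
        exactly on circles of radius R, equiangular starting at phase_deg.
        """
        az = np.deg2rad(self.phase_deg + 360.0 * np.arange(self.beads_per_ring)
                        / self.beads_per_ring)
        r = self.radius
        ring = np.column_stack([r * np.cos(az), r * np.sin(az)])
        up = np.column_stack([ring, np.full(len(az), self.ring_separation / 2)])
        lo = np.column_stack([ring, np.full(len(az), -self.ring_separation / 2)])
        return up, lo


@dataclass
class CalibProjection:
    """One simulated phantom projection plus its ground truth."""

    image: np.ndarray  # (n_v, n_h)
    true_upper: np.ndarray  # (n_beads, 2) pixel (h, v) of upper-ring beads
    true_lower: np.ndarray
    off_detector: np.ndarray  # bool flags, upper ring then lower
    geometry: ViewGeometry | None = None


def _gaussian_blob(img, hc, vc, sigma, amp):
    n_v, n_h = img.shape
    r = max(int(np.ceil(4 * sigma)), 2)
    h0, h1 = int(np.floor(hc)) - r, int(np.floor(hc)) + r + 1
    v0, v1 = int(np.floor(vc)) - r, int(np.floor(vc)) + r + 1
    h0, h1 = max(h0, 0), min(h1, n_h)
    v0, v1 = max(v0, 0), min(v1, n_v)
    if h0 >= h1 or v0 >= v1:
        return
    hh = np.arange(h0, h1)
    vv = np.arange(v0, v1)
    g = np.exp(
        -((hh[None, :] - hc) ** 2 + (vv[:, None] - vc) ** 2) / (2 * sigma**2)
    )
    img[v0:v1, h0:h1] += amp * g


def _ray_sphere_chords(starts, dirs, center, radius):
    """Chord lengths of unit-direction rays through a sphere (vectorised)."""
    oc = starts - center
    b = np.einsum("ij,ij->i", oc, dirs)
    c = np.einsum("ij,ij->i", oc, oc) - radius**2
    disc = b * b - c
    return 2.0 * np.sqrt(np.maximum(disc, 0.0))


def _ray_cyl_interval(starts, dirs, radius):
    """Entry/exit parameters of rays through an infinite z-cylinder."""
    a = dirs[:, 0] ** 2 + dirs[:, 1] ** 2
    b = starts[:, 0] * dirs[:, 0] + starts[:, 1] * dirs[:, 1]
    c = starts[:, 0] ** 2 + starts[:, 1] ** 2 - radius**2
    disc = b * b - a * c
    ok = (disc > 0) & (a > 0)
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.where(ok, (-b - sq) / a, 0.0)
        t1 = np.where(ok, (-b + sq) / a, 0.0)
    return t0, t1, ok


def _clip_by_z(starts, dirs, t0, t1, z_lo, z_hi):
    """Intersect ray-parameter intervals with the slab z in [z_lo, z_hi]."""
    dz = dirs[:, 2]
    sz = starts[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (z_lo - sz) / dz
        tb = (z_hi - sz) / dz
    lo = np.where(dz >= 0, ta, tb)
    hi = np.where(dz >= 0, tb, ta)
    flat = np.abs(dz) < 1e-12
    inside = (sz >= z_lo) & (sz <= z_hi)
    lo = np.where(flat, np.where(inside, -np.inf, np.inf), lo)
    hi = np.where(flat, np.where(inside, np.inf, -np.inf), hi)
    return np.maximum(t0, lo), np.minimum(t1, hi)


def simulate_calib_projection(
    spec: CalibPhantomSpec,
    geom: ViewGeometry,
    detector: DetectorSpec,
    mode: str = "analytic",
    supersample: int = 3,
) -> CalibProjection:
    """Render one projection of the BB phantom.

    ``analytic`` draws each bead as a 2-D Gaussian blob centred exactly at
    the perspective projection of its centre (sigma = projected bead
    radius) — the ground-truth centroids are those projections, which makes
    this renderer the oracle for the marker-detection pipeline.
    ``raytraced`` line-integrates the full phantom (beads as exact
    ray-sphere chords, PMMA wall as a finite cylinder shell) on a
    supersampled pixel grid.
    """
    up, lo = spec.bead_centers()
    centers = np.vstack([up, lo])
    pix = project_points(geom, detector, centers)
    off = (
        (pix[:, 0] < 0)
        | (pix[:, 0] > detector.n_h - 1)
        | (pix[:, 1] < 0)
        | (pix[:, 1] > detector.n_v - 1)
    )
    if off.any():
        warnings.warn(f"{int(off.sum())} bead(s) project outside the detector")
    img = np.zeros((detector.n_v, detector.n_h), np.float32)
    if mode == "analytic":
        r_bead = spec.bead_diameter / 2.0
        for (hc, vc), c in zip(pix, centers):
            mag = geom.sdd / np.linalg.norm(c - geom.source_pos)
            sigma = max(r_bead * mag / detector.pixel_size, 0.7)
            _gaussian_blob(img, hc, vc, sigma, 2 * r_bead * spec.bead_attenuation)
    elif mode == "raytraced":
        img = _raytrace_phantom(spec, geom, detector, centers, supersample)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nb = spec.beads_per_ring
    return CalibProjection(
        image=img,
        true_upper=pix[:nb],
        true_lower=pix[nb:],
        off_detector=off,
        geometry=geom,
    )


def _raytrace_phantom(spec, geom, detector, centers, ss):
    e_h, e_v, _ = geom.detector_basis()
    px = detector.pixel_size
    n_v, n_h = detector.n_v, detector.n_h
    sub = (np.arange(ss) - (ss - 1) / 2.0) / ss
    img = np.zeros((n_v, n_h))
    src = geom.source_pos
    for dv in sub:
        for dh in sub:
            hh, vv = np.meshgrid(
                (np.arange(n_h) + dh - detector.center_h) * px,
                (np.arange(n_v) + dv - detector.center_v) * px,
            )
            pts = (
                geom.detector_pos
                + hh.ravel()[:, None] * e_h
                + vv.ravel()[:, None] * e_v
            )
            dirs = pts - src
            norm = np.linalg.norm(dirs, axis=1, keepdims=True)
            dirs = dirs / norm
            starts = np.broadcast_to(src, dirs.shape)
            acc = np.zeros(len(dirs))
            r_bead = spec.bead_diameter / 2.0
            for c in centers:
                acc += spec.bead_attenuation * _ray_sphere_chords(
                    starts, dirs, c, r_bead
                )
            # PMMA wall: outer minus inner cylinder, limited in z
            half = spec.ring_separation / 2.0 + 5.0
            for radius, sign in (
                (spec.cyl_outer_diameter / 2, 1.0),
                (spec.cyl_inner_diameter / 2, -1.0),
            ):
                t0, t1, ok = _ray_cyl_interval(starts, dirs, radius)
                t0, t1 = _clip_by_z(starts, dirs, t0, t1, -half, half)
                chord = np.where(ok, np.maximum(t1 - t0, 0.0), 0.0)
                acc += sign * spec.wall_attenuation * chord
            img += acc.reshape(n_v, n_h)
    return (img / ss**2).astype(np.float32)


def simulate_calib_scan(
    spec: CalibPhantomSpec, traj: Trajectory, mode: str = "analytic"
) -> tuple[ProjectionSet, list[CalibProjection]]:
    """Phantom projections at every angular position of a trajectory."""
    projs = [
        simulate_calib_projection(spec, g, traj.detector, mode=mode)
        for g in traj
    ]
    stack = np.stack([p.image for p in projs])
    return ProjectionSet(stack, traj, {"content": "calib_phantom"}), projs


# ---------------------------------------------------------------------------
# anatomical-like test objects
# ---------------------------------------------------------------------------

SOFT_MU = 0.02  # 1/mm, soft tissue at ~60 keV
BONE_MU = 0.05  # 1/mm, cortical-bone-like


@dataclass
class DigitalSample:
    """Analytic test object: attenuation volume plus its exact support."""

    volume: Volume
    support: SurfaceMask
    kind: str = ""
    seed: int | None = None


def _ellipsoid_mask(xx, yy, zz, center, semi):
    return (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_digital_sample(
    kind: str = "ellipsoid-limb",
    size: int = 128,
    voxel_size: float = 1.0,
    seed: int | None = None,
) -> DigitalSample:
    """Deterministic two-material test object built from analytic primitives.

    ``ellipsoid-limb`` mimics an extremity: a soft-tissue ellipsoid with two
    bone-like ellipsoidal inserts.  ``bar`` is a soft slab with two dense
    rods.  Attenuations are exactly two levels (soft, bone) before any
    smoothing, and the returned support is the exact union of primitives.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(seed)
    n = int(size)
    vol = Volume(np.zeros((n, n, n), np.float32), voxel_size)
    x, y, z = vol.world_coords()
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    ext = n * voxel_size / 2.0
    data = vol.data
    if kind == "ellipsoid-limb":
        jit = rng.uniform(0.95, 1.05, 3)
        outer = _ellipsoid_mask(
            xx, yy, zz, (0, 0, 0),
            (0.5 * ext * jit[0], 0.38 * ext * jit[1], 0.72 * ext),
        )
        b1 = _ellipsoid_mask(
            xx, yy, zz, (0.16 * ext, 0.08 * ext, 0),
            (0.12 * ext, 0.1 * ext, 0.6 * ext),
        )
        b2 = _ellipsoid_mask(
            xx, yy, zz, (-0.18 * ext * jit[2], -0.06 * ext, 0),
            (0.09 * ext, 0.08 * ext, 0.55 * ext),
        )
        support = outer.copy()
        # finger-like digits: soft-tissue cylinders with a thin bone core,
        # protruding past one end of the limb (they make the silhouette
        # feature-rich, the way a hand or foot is)
        digit_x = np.array([-0.3, -0.05, 0.22]) * ext
        digit_len = np.array([0.92, 1.0, 0.85]) * ext * rng.uniform(
            0.95, 1.05, 3
        )
        for dxc, dl in zip(digit_x, digit_len):
            dig = (
                ((xx - dxc) ** 2 + yy**2 <= (0.07 * ext) ** 2)
                & (zz >= 0.3 * ext) & (zz <= dl)
            )
            support |= dig
            data[dig] = SOFT_MU
            core = (
                ((xx - dxc) ** 2 + yy**2 <= (0.03 * ext) ** 2)
                & (zz >= 0.3 * ext) & (zz <= dl - 0.03 * ext)
            )
            b1 = b1 | core
        data[outer] = SOFT_MU
        data[b1 | b2] = BONE_MU
    elif kind == "bar":
        slab = (
            (np.abs(xx) <= 0.5 * ext)
            & (np.abs(yy) <= 0.3 * ext)
            & (np.abs(zz) <= 0.7 * ext)
        )
        r1 = ((xx - 0.25 * ext) ** 2 + yy**2) <= (0.08 * ext) ** 2
        r2 = ((xx + 0.25 * ext) ** 2 + yy**2) <= (0.08 * ext) ** 2
        rods = (r1 | r2) & (np.abs(zz) <= 0.7 * ext)
        data[slab] = SOFT_MU
        data[rods] = BONE_MU
        support = slab
    else:
        raise ValueError(f"unknown sample kind {kind!r}")
    return DigitalSample(
        volume=vol,
        support=SurfaceMask(support, voxel_size, vol.origin.copy()),
        kind=kind,
        seed=seed,
    )


def simulate_scan(
    sample: DigitalSample | Volume,
    traj: Trajectory,
    noise: str | None = None,
    i0: float = 1e5,
    seed: int | None = None,
) -> ProjectionSet:
    """Cone-beam scan of a digital sample: line integrals, optional noise.

    With ``noise='poisson'`` transmitted counts ``I0*exp(-p)`` are Poisson
    sampled and log-converted back to line integrals; ``noise=None`` is
    exactly deterministic.
    """
    vol = sample.volume if isinstance(sample, DigitalSample) else sample
    op = SystemOperator(traj, vol.shape, vol.voxel_size, vol.origin)
    proj = op.forward(vol)
    proj.meta["units"] = "line_integral"
    if noise in (None, "none"):
        return proj
    if noise != "poisson":
        raise ValueError(f"unknown noise model {noise!r}")
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(i0 * np.exp(-proj.data.astype(np.float64)))
    noisy = -np.log(np.maximum(counts, 0.5) / i0)
    out = proj.copy_with(noisy.astype(np.float32))
    out.meta.update({"units": "line_integral", "noise": "poisson", "i0": i0})
    return out


# ---------------------------------------------------------------------------
# image-intensifier distortion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensifierDistortion:
    """Anisotropic scaling of an image-intensifier projection.

    A circular object appears elongated along the vertical axis by
    ``factor``.  Older mobile C-arm image intensifiers commonly show a
    major/minor diameter difference of a few percent; the default models an
    8 % elongation (factor 1.08).
    """

    factor: float = 1.08

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("distortion factor must be positive")


def _scale_v(img: np.ndarray, scale: float, order: int = 1) -> np.ndarray:
    """Scale the vertical (row) axis by ``scale`` about the image centre."""
    n_v = img.shape[0]
    c = (n_v - 1) / 2.0
    rows = (np.arange(n_v) - c) / scale + c
    coords = np.meshgrid(rows, np.arange(img.shape[1]), indexing="ij")
    return ndimage.map_coordinates(
        img.astype(np.float64), coords, order=order, mode="constant"
    )


def apply_intensifier_distortion(
    img: np.ndarray, d: IntensifierDistortion
) -> np.ndarray:
    """Stretch the vertical axis by the distortion factor (Eq.-17 model)."""
    return _scale_v(img, d.factor)


def correct_intensifier_distortion(
    img: np.ndarray, d: IntensifierDistortion
) -> np.ndarray:
    """Undo the intensifier stretch so circles become circular again."""
    return _scale_v(img, 1.0 / d.factor)


# ---------------------------------------------------------------------------
# mesh voxelization
# ---------------------------------------------------------------------------

def voxelize_mesh(mesh, shape, voxel_size: float, origin=None) -> SurfaceMask:
    """Binary mask of a watertight triangle mesh on a voxel grid.

    A voxel is inside when its centre is contained in the mesh, decided by
    parity counting of +z ray/triangle crossings per voxel column.
    """
    if not getattr(mesh, "is_watertight", False):
        raise ValueError(
            "mesh is not watertight (open boundary or duplicate faces); "
            "repair it before voxelization"
        )
    tmpl = Volume(np.zeros(tuple(shape), np.uint8), voxel_size, origin)
    x, y, z = tmpl.world_coords()
    nx, ny, nz = tmpl.data.shape
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces)
    # tiny shear breaks ray-through-edge degeneracies deterministically
    eps = 1e-9 * max(voxel_size, 1.0)
    crossings: dict[tuple[int, int], list[float]] = {}
    for f in faces:
        a, b, c = verts[f]
        x0 = max(int(np.ceil((min(a[0], b[0], c[0]) - x[0]) / voxel_size)), 0)
        x1 = min(int(np.floor((max(a[0], b[0], c[0]) - x[0]) / voxel_size)),
                 nx - 1)
        y0 = max(int(np.ceil((min(a[1], b[1], c[1]) - y[0]) / voxel_size)), 0)
        y1 = min(int(np.floor((max(a[1], b[1], c[1]) - y[0]) / voxel_size)),
                 ny - 1)
        if x0 > x1 or y0 > y1:
            continue
        e1 = b[:2] - a[:2]
        e2 = c[:2] - a[:2]
        det = e1[0] * e2[1] - e1[1] * e2[0]
        if abs(det) < 1e-15:
            continue  # triangle vertical to the ray direction
        gx = x[x0 : x1 + 1]
        gy = y[y0 : y1 + 1]
        px = gx[:, None] - a[0] + eps
        py = gy[None, :] - a[1] + eps
        s = (px * e2[1] - py * e2[0]) / det
        t = (-px * e1[1] + py * e1[0]) / det
        inside = (s >= 0) & (t >= 0) & (s + t <= 1)
        if not inside.any():
            continue
        zc = a[2] + s * (b[2] - a[2]) + t * (c[2] - a[2])
        ii, jj = np.nonzero(inside)
        for i, j, zv in zip(ii, jj, zc[inside]):
            crossings.setdefault((x0 + i, y0 + j), []).append(zv)
    out = np.zeros((nx, ny, nz), bool)
    for (i, j), zs in crossings.items():
        zs = sorted(zs)
        for k in range(0, len(zs) - 1, 2):
            out[i, j, :] |= (z >= zs[k]) & (z < zs[k + 1])
    return SurfaceMask(out, voxel_size, tmpl.origin.copy())
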