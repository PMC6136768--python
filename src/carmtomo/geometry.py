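"""Coordinate system and per-view acquisition geometry.

World frame
-----------
The origin sits at the centre of the calibration phantom (the nominal
isocenter) with ``z`` along the phantom axis.  For a nominal gantry angle
``beta`` (degrees) the source lies in the ``z = 0`` midplane at
``SOD * (cos beta, sin beta, 0)``.

Detector frame
--------------
Seen from the source, ``h`` points right and ``v`` points up.  For an ideal
view the detector basis is::

    e_h = (-sin beta,  cos beta, 0)
    e_v = (0, 0, 1)
    n   = ( cos beta,  sin beta, 0)      # unit normal, pointing at the source

Misalignments are applied to this basis as extrinsic rotations in the fixed
ideal axes, in the order roll -> pitch -> skew:

* roll ``phi``   : rotation about ``e_v`` (vertical axis of the panel),
* pitch ``theta``: rotation about ``e_h`` (horizontal axis of the panel),
* skew ``eta``   : in-plane rotation about the normal ``n``.

In-plane offsets ``offset_h`` / ``offset_v`` (pixels) translate the detector
centre inside the (rotated) detector plane.  Angles are degrees externally
and converted to radians only inside computations.  Pixel coordinates are
0-based with the pixel-centre convention; millimetre detector coordinates are
measured from the detector centre along ``e_h`` / ``e_v``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "DetectorSpec",
    "ViewGeometry",
    "Trajectory",
    "GeometryPerturbation",
    "make_view_geometry",
    "make_circular_trajectory",
    "perturb_trajectory",
    "unperturb_trajectory",
    "project_point",
    "project_points",
    "save_geometry",
    "load_geometry",
]

GEOMETRY_SCHEMA_VERSION = 1


class GeometryError(ValueError):
    """Raised for non-physical or inconsistent geometry parameters."""


@dataclass(frozen=True)
class DetectorSpec:
    """Flat-panel description: pixel counts, pitch and centre.

    ``center_h`` / ``center_v`` (``O_h``, ``O_v``) are the pixel coordinates
    of the detector centre; by default the geometric centre of the grid.
    """

    n_h: int
    n_v: int
    pixel_size: float  # mm / pixel, isotropic
    center_h: float = -1.0
    center_v: float = -1.0

    def __post_init__(self):
        if self.n_h <= 0 or self.n_v <= 0:
            raise GeometryError("pixel counts must be positive")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if self.center_h < 0:
            object.__setattr__(self, "center_h", (self.n_h - 1) / 2.0)
        if self.center_v < 0:
            object.__setattr__(self, "center_v", (self.n_v - 1) / 2.0)
        if not (0 <= self.center_h <= self.n_h - 1) or not (
            0 <= self.center_v <= self.n_v - 1
        ):
            raise GeometryError("detector centre outside the pixel grid")

    @property
    def width_mm(self) -> float:
        return self.n_h * self.pixel_size

    @property
    def height_mm(self) -> float:
        return self.n_v * self.pixel_size


def _rot(axis: np.ndarray, deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues), angle in degrees."""
    t = np.deg2rad(deg)
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)


@dataclass
class ViewGeometry:
    """Pose of the source/detector pair for a single projection."""

    angle: float  # nominal gantry angle, degrees
    source_pos: np.ndarray  # (3,) mm
    detector_pos: np.ndarray  # (3,) mm, detector centre
    sdd: float  # source-to-detector distance, mm
    skew: float = 0.0  # eta, degrees
    pitch: float = 0.0  # theta, degrees
    roll: float = 0.0  # phi, degrees
    offset_h: float = 0.0  # H, pixels
    offset_v: float = 0.0  # V, pixels
    piercing_h: float = 0.0  # mm from detector centre along e_h
    piercing_v: float = 0.0  # mm from detector centre along e_v

    def __post_init__(self):
        self.source_pos = np.asarray(self.source_pos, dtype=float)
        self.detector_pos = np.asarray(self.detector_pos, dtype=float)
        if self.sdd <= 0:
            raise GeometryError("sdd must be positive")
        for name in ("skew", "pitch", "roll"):
            if abs(getattr(self, name)) >= 90.0:
                raise GeometryError(f"|{name}| must be < 90 degrees")

    # -- detector basis ----------------------------------------------------
    def detector_basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit vectors (e_h, e_v, n) of the misaligned detector."""
        b = np.deg2rad(self.angle)
        e_h0 = np.array([-np.sin(b), np.cos(b), 0.0])
        e_v0 = np.array([0.0, 0.0, 1.0])
        n0 = np.array([np.cos(b), np.sin(b), 0.0])
        R = _rot(n0, self.skew) @ _rot(e_h0, self.pitch) @ _rot(e_v0, self.roll)
        return R @ e_h0, R @ e_v0, R @ n0

    def copy(self) -> "ViewGeometry":
        return ViewGeometry(
            angle=self.angle,
            source_pos=self.source_pos.copy(),
            detector_pos=self.detector_pos.copy(),
            sdd=self.sdd,
            skew=self.skew,
            pitch=self.pitch,
            roll=self.roll,
            offset_h=self.offset_h,
            offset_v=self.offset_v,
            piercing_h=self.piercing_h,
            piercing_v=self.piercing_v,
        )


@dataclass
class Trajectory:
    """Ordered set of views sharing one detector."""

    views: list[ViewGeometry]
    detector: DetectorSpec
    angular_span: float = 0.0

    def __post_init__(self):
        if len(self.views) < 2:
            raise GeometryError("a trajectory needs at least 2 views")
        angles = np.array([v.angle for v in self.views])
        d = np.diff(angles)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise GeometryError("view angles must be strictly monotone")
        if self.angular_span == 0.0:
            self.angular_span = float(abs(angles[-1] - angles[0]))

    def __len__(self) -> int:
        return len(self.views)

    def __iter__(self):
        return iter(self.views)

    @property
    def angles(self) -> np.ndarray:
        return np.array([v.angle for v in self.views])

    def copy(self) -> "Trajectory":
        return Trajectory(
            [v.copy() for v in self.views], self.detector, self.angular_span
        )


@dataclass
class GeometryPerturbation:
    """Per-view detector-plane perturbations (ΔH, ΔV px; ΔS degrees).

    Models the shot-to-shot non-repeatability of the source/detector pose of
    a hand-moved C-arm.  Reproducible: ``random`` is fully determined by its
    seed and bounds.
    """

    dh: np.ndarray
    dv: np.ndarray
    ds: np.ndarray
    seed: int | None = None
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dh = np.atleast_1d(np.asarray(self.dh, dtype=float))
        self.dv = np.atleast_1d(np.asarray(self.dv, dtype=float))
        self.ds = np.atleast_1d(np.asarray(self.ds, dtype=float))
        if not (len(self.dh) == len(self.dv) == len(self.ds)):
            raise GeometryError("perturbation arrays must share one length")

    def __len__(self) -> int:
        return len(self.dh)

    @classmethod
    def zero(cls, n_views: int) -> "GeometryPerturbation":
        z = np.zeros(n_views)
        return cls(z, z.copy(), z.copy())

    @classmethod
    def random(
        cls,
        n_views: int,
        dh_max: float = 10.0,
        dv_max: float = 10.0,
        ds_max: float = 3.0,
        seed: int | None = None,
    ) -> "GeometryPerturbation":
        rng = np.random.default_rng(seed)
        return cls(
            dh=rng.uniform(-dh_max, dh_max, n_views),
            dv=rng.uniform(-dv_max, dv_max, n_views),
            ds=rng.uniform(-ds_max, ds_max, n_views),
            seed=seed,
            bounds={"dh_max": dh_max, "dv_max": dv_max, "ds_max": ds_max},
        )


def make_view_geometry(
    angle: float,
    sdd: float,
    sod: float,
    detector: DetectorSpec,
    skew: float = 0.0,
    pitch: float = 0.0,
    roll: float = 0.0,
    offset_h: float = 0.0,
    offset_v: float = 0.0,
) -> ViewGeometry:
    """Assemble a self-consistent ViewGeometry from scan parameters.

    The detector centre sits on the source->origin ray at distance ``sdd``
    from the source, then is rotated (roll, pitch, skew about the ideal axes)
    and translated in-plane by the pixel offsets.  The piercing point (image
    of the world origin) is recomputed from the final pose.
    """
    if not (0 < sod < sdd):
        raise GeometryError("need 0 < sod < sdd")
    g = ViewGeometry(
        angle=angle,
        source_pos=np.zeros(3),
        detector_pos=np.zeros(3),
        sdd=sdd,
        skew=skew,
        pitch=pitch,
        roll=roll,
        offset_h=offset_h,
        offset_v=offset_v,
    )
    b = np.deg2rad(angle)
    u = np.array([np.cos(b), np.sin(b), 0.0])  # origin -> source direction
    g.source_pos = sod * u
    e_h, e_v, _ = g.detector_basis()
    c0 = g.source_pos - sdd * u  # ideal centre, on the central ray
    px = detector.pixel_size
    g.detector_pos = c0 + offset_h * px * e_h + offset_v * px * e_v
    # piercing point: central ray (source through origin) hits the plane
    p_h, p_v = _plane_coords(g, np.zeros(3))
    g.piercing_h = p_h
    g.piercing_v = p_v
    return g


def make_circular_trajectory(
    n_views: int,
    span: float,
    sdd: float,
    sod: float,
    detector: DetectorSpec,
    start_angle: float = 0.0,
) -> Trajectory:
    """Ideal isocentric arc: ``n_views`` equally spaced over ``span`` degrees.

    Views are spaced ``span / (n_views - 1)`` apart for a partial arc and
    ``span / n_views`` for a full 360° orbit (end point excluded).
    """
    if n_views < 2:
        raise GeometryError("n_views must be >= 2")
    if not (0 < span <= 360):
        raise GeometryError("span must be in (0, 360] degrees")
    if span == 360.0:
        angles = start_angle + np.arange(n_views) * (span / n_views)
    else:
        angles = start_angle + np.linspace(0.0, span, n_views)
    views = [make_view_geometry(a, sdd, sod, detector) for a in angles]
    return Trajectory(views, detector, angular_span=span)


def perturb_trajectory(traj: Trajectory, pert: GeometryPerturbation) -> Trajectory:
    """Shift each view's offsets/skew by the recorded amounts (invertible)."""
    if len(pert) != len(traj):
        raise GeometryError(
            f"perturbation length {len(pert)} != view count {len(traj)}"
        )
    out = []
    for g, dh, dv, ds in zip(traj.views, pert.dh, pert.dv, pert.ds):
        sod = float(np.linalg.norm(g.source_pos))
        out.append(
            make_view_geometry(
                g.angle,
                g.sdd,
                sod,
                traj.detector,
                skew=g.skew + ds,
                pitch=g.pitch,
                roll=g.roll,
                offset_h=g.offset_h + dh,
                offset_v=g.offset_v + dv,
            )
        )
    return Trajectory(out, traj.detector, traj.angular_span)


def unperturb_trajectory(traj: Trajectory, pert: GeometryPerturbation) -> Trajectory:
    """Exact inverse of :func:`perturb_trajectory` given the same record."""
    inv = GeometryPerturbation(-pert.dh, -pert.dv, -pert.ds)
    return perturb_trajectory(traj, inv)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _plane_coords(geom: ViewGeometry, p: np.ndarray) -> tuple[float, float]:
    """(h, v) in mm from the detector centre for world point(s) ``p``."""
    e_h, e_v, n = geom.detector_basis()
    s = geom.source_pos
    d = np.atleast_2d(p) - s
    denom = d @ n
    num = (geom.detector_pos - s) @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise GeometryError("ray parallel to the detector plane or behind source")
    hit = s + t[:, None] * d - geom.detector_pos
    h = hit @ e_h
    v = hit @ e_v
    if np.ndim(p) == 1:
        return float(h[0]), float(v[0])
    return h, v


def project_point(
    geom: ViewGeometry, detector: DetectorSpec, p: Sequence[float]
) -> tuple[float, float]:
    """Perspective projection of a world point onto the detector, in pixels."""
    h_mm, v_mm = _plane_coords(geom, np.asarray(p, dtype=float))
    px = detector.pixel_size
    return detector.center_h + h_mm / px, detector.center_v + v_mm / px


def project_points(
    geom: ViewGeometry, detector: DetectorSpec, pts: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`project_point` for an (N, 3) array; returns (N, 2)."""
    h_mm, v_mm = _plane_coords(geom, np.asarray(pts, dtype=float))
    px = detector.pixel_size
    return np.column_stack(
        [detector.center_h + h_mm / px, detector.center_v + v_mm / px]
    )


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def _view_record(g: ViewGeometry) -> dict:
    return {
        "angle_deg": g.angle,
        "source_pos_mm": list(g.source_pos),
        "detector_pos_mm": list(g.detector_pos),
        "sdd_mm": g.sdd,
        "skew_deg": g.skew,
        "pitch_deg": g.pitch,
        "roll_deg": g.roll,
        "offset_h_px": g.offset_h,
        "offset_v_px": g.offset_v,
        "piercing_h_mm": g.piercing_h,
        "piercing_v_mm": g.piercing_v,
    }


def save_geometry(traj: Trajectory, path) -> None:
    doc = {
        "schema_version": GEOMETRY_SCHEMA_VERSION,
        "angular_span_deg": traj.angular_span,
        "detector": asdict(traj.detector),
        "views": [_view_record(g) for g in traj.views],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_geometry(path) -> Trajectory:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != GEOMETRY_SCHEMA_VERSION:
        raise GeometryError("unknown geometry schema version")
    det = DetectorSpec(**doc["detector"])
    views = [
        ViewGeometry(
            angle=r["angle_deg"],
            source_pos=np.array(r["source_pos_mm"]),
            detector_pos=np.array(r["detector_pos_mm"]),
            sdd=r["sdd_mm"],
            skew=r["skew_deg"],
            pitch=r["pitch_deg"],
            roll=r["roll_deg"],
            offset_h=r["offset_h_px"],
            offset_v=r["offset_v_px"],
            piercing_h=r["piercing_h_mm"],
            piercing_v=r["piercing_v_mm"],
        )
        for r in doc["views"]
    ]
    return Trajectory(views, det, doc["angular_span_deg"])
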