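"""Per-projection geometric calibration from the two-ring BB phantom.

For every projection of the calibration phantom the pipeline runs six
steps: (1) marker centre-of-mass detection, (2) ellipse fitting of the two
projected rings, (3) piercing-point (v-h offset) determination, (4) skew
angle, (5) detector inclination angles — pitch from the tangent-line
converging point of the two ellipses, roll by simplex minimization of a
convergence cost on the ellipse long axes — and (6) source and detector
positions.  Each step is exposed and validated against the analytic
simulator, which is the accuracy contract for the whole module; a final
Levenberg-Marquardt polish matches the two measured conics to analytically
projected ring conics over all seven per-view parameters.

The pitch relation deserves a note.  With ``v_theta`` the distance from the
piercing point to the tangent converging point P_theta measured along the
projected phantom axis, and ``Z_S = 2 R L1 L2 / (H (L2 - L1))`` computed
from the inner gap ``L1`` and outer span ``L2`` of the two ellipses along
that axis, the exact projective relations for this phantom are

    sin(theta) = SDD / v_theta,      Z_S ~= SDD / cos(theta),

so the pitch follows from ``tan(theta) = Z_S cos(phi) / v_theta`` (exact up
to an O((H tan(theta) / Z)^2) term, 0.06 degrees at theta = 60 degrees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares, minimize
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .containers import ProjectionSet
from .ellipse import (
    EllipseFit,
    EllipseFitError,
    common_tangents,
    fit_ellipse,
    intersect_lines,
)
from .geometry import (
    DetectorSpec,
    Trajectory,
    ViewGeometry,
    make_view_geometry,
    project_points,
)
from .phantoms import CalibPhantomSpec

__all__ = [
    "MarkerSet",
    "EllipsePair",
    "RollCostParams",
    "CalibrationError",
    "segment_markers",
    "classify_rings",
    "make_ellipse_pair",
    "estimate_offsets_and_skew",
    "estimate_pitch",
    "estimate_roll",
    "estimate_source_detector",
    "calibrate_view",
    "calibrate_scan",
    "predict_ellipse_pair",
]

# relative |L2-L1| threshold below which pitch is declared zero
PITCH_DEGENERACY_RTOL = 1e-3


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# step 1: marker segmentation
# ---------------------------------------------------------------------------

@dataclass
class MarkerSet:
    """Detected bead centroids, optionally labelled by ring.

    ``weights`` counts the beads behind each centroid: 1 for a resolved
    bead, 2 for an unresolvable merged pair (two beads projecting on top of
    each other), whose centroid is the mean of the two bead projections.
    """

    centroids: np.ndarray  # (N, 2) as (h, v) pixels
    labels: np.ndarray | None = None  # 0 = upper ring, 1 = lower ring
    threshold: float = float("nan")
    weights: np.ndarray | None = None
    sigma: float = float("nan")  # estimated bead blob width, px

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.weights is None:
            self.weights = np.ones(len(self.centroids))
        self.weights = np.asarray(self.weights, dtype=float)

    def __len__(self) -> int:
        return len(self.centroids)

    @property
    def n_beads(self) -> int:
        return int(self.weights.sum())

    def ring(self, which: str, singles_only: bool = False) -> np.ndarray:
        if self.labels is None:
            raise CalibrationError("markers are not classified into rings yet")
        idx = 0 if which == "upper" else 1
        sel = self.labels == idx
        if singles_only:
            sel &= self.weights == 1
        return self.centroids[sel]


def _component_centroid(img, labels, lab, bbox, thr):
    """Sub-pixel centroid and integrated mass of one blob.

    Threshold-subtracted centre of mass over the component dilated by 2 px.
    For a symmetric blob the weight (I - thr)+ is symmetric about the true
    centre, so the estimate is unbiased; the dilation recovers the mass
    clipped by the threshold.  The integrated mass is proportional to the
    number of beads in the blob (beads have equal integrals), which makes
    it a sharp single/merged-pair discriminator even at full overlap."""
    n_v, n_h = img.shape
    v0, h0, v1, h1 = bbox
    pad = 3
    v0, h0 = max(v0 - pad, 0), max(h0 - pad, 0)
    v1, h1 = min(v1 + pad, n_v), min(h1 + pad, n_h)
    mask = labels[v0:v1, h0:h1] == lab
    mask = ndimage.binary_dilation(mask, iterations=2)
    w = np.clip(img[v0:v1, h0:h1] - thr, 0.0, None) * mask
    tot = w.sum()
    if tot <= 0:
        return None
    hh = np.arange(h0, h1)
    vv = np.arange(v0, v1)
    h = float((w * hh[None, :]).sum() / tot)
    v = float((w * vv[:, None]).sum() / tot)
    return h, v, float(tot)


def _fit_two_gaussians(img, labels, labs, bbox, thr, sigma0, init_centers):
    """Resolve two overlapping beads by fitting a two-Gaussian mixture.

    The bead image model is a Gaussian blob, so a mixture fit recovers the
    two centres accurately down to ~1 px separation; below that the blob is
    indistinguishable from a single wider Gaussian and ``None`` is
    returned (the caller falls back to the weight-2 joint centroid).
    """
    n_v, n_h = img.shape
    v0, h0, v1, h1 = bbox
    pad = 4
    v0, h0 = max(v0 - pad, 0), max(h0 - pad, 0)
    v1, h1 = min(v1 + pad, n_v), min(h1 + pad, n_h)
    win = img[v0:v1, h0:h1]
    mask = np.isin(labels[v0:v1, h0:h1], labs)
    mask = ndimage.binary_dilation(mask, iterations=2)
    if mask.sum() < 8:
        return None
    hh, vv = np.meshgrid(np.arange(h0, h1), np.arange(v0, v1))
    mh, mv, mi = hh[mask], vv[mask], win[mask]
    (h1c, v1c), (h2c, v2c) = init_centers
    amp0 = float(mi.max())

    def model(x):
        a1, a2, x1, y1, x2, y2, sg = x
        g1 = a1 * np.exp(-((mh - x1) ** 2 + (mv - y1) ** 2) / (2 * sg**2))
        g2 = a2 * np.exp(-((mh - x2) ** 2 + (mv - y2) ** 2) / (2 * sg**2))
        return g1 + g2 - mi

    x0 = [amp0, amp0, h1c, v1c, h2c, v2c, max(sigma0, 0.5)]
    try:
        res = least_squares(
            model, x0, method="lm", xtol=1e-10, ftol=1e-10, max_nfev=200
        )
    except Exception:
        return None
    a1, a2, x1, y1, x2, y2, sg = res.x
    sg = abs(sg)
    sep = np.hypot(x2 - x1, y2 - y1)
    rel = np.linalg.norm(res.fun) / max(np.linalg.norm(mi), 1e-9)
    if sep < 1.0 or rel > 0.1 or min(a1, a2) < 0.2 * amp0:
        return None
    if not (0.6 * sigma0 < sg < 1.6 * sigma0):
        return None  # sub-pixel pair masquerading as a wide/narrow split
    return [(float(x1), float(y1)), (float(x2), float(y2))]


def segment_markers(
    img: np.ndarray,
    threshold: float | None = None,
    overrides: dict | None = None,
) -> MarkerSet:
    """Threshold-based bead detection with morphological cleaning.

    Otsu threshold (overridable), binary opening, an area filter around the
    median blob area, and an eccentricity filter; centroids are
    intensity-weighted centres of mass.  Blobs whose area marks them as two
    merged beads are rejected rather than split, and centroid pairs closer
    than one bead footprint are dropped — programmatic stand-ins for the
    interactive corrections of a GUI tool.  ``overrides`` may carry
    ``add`` (list of (h, v) centroids) and ``remove`` (list of (h, v);
    nearest detection is deleted).
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise CalibrationError("projection contains non-finite values")
    if img.max() <= img.min():
        return MarkerSet(np.empty((0, 2)), threshold=float("nan"))
    thr = float(threshold) if threshold is not None else float(threshold_otsu(img))
    binary = img > thr
    opened = ndimage.binary_opening(binary)
    labels_o = sk_label(opened)
    # opening can erase small beads entirely; fall back when it does
    if labels_o.max() < sk_label(binary).max() / 2:
        labels_o = sk_label(binary)
    props = regionprops(labels_o, intensity_image=img)
    if not props:
        return MarkerSet(np.empty((0, 2)), threshold=thr)
    raw = []
    for p in props:
        hvm = _component_centroid(img, labels_o, p.label, p.bbox, thr)
        if hvm is not None:
            raw.append(
                (hvm[0], hvm[1], hvm[2], p.area, p.eccentricity,
                 p.label, p.bbox, np.degrees(p.orientation))
            )
    if not raw:
        return MarkerSet(np.empty((0, 2)), threshold=thr)
    masses = np.array([r[2] for r in raw])
    # single-bead mass from the lower quartile: in crowded views more than
    # half the blobs can be merged pairs, which would poison a median
    m1 = max(float(np.percentile(masses, 25)), 1e-12)
    a1 = max(float(np.percentile([r[3] for r in raw], 25)), 1.0)
    sigma0 = np.sqrt(a1 / np.pi) / 1.2  # rough Gaussian width of a bead
    cents, wts, labs = [], [], []
    for h, v, mass, area, ecc, lab, bbox, orient in raw:
        n_est = mass / m1
        if n_est < 0.3:
            continue  # dust
        if n_est <= 1.5:
            if ecc > 0.95:
                continue
            cents.append((h, v))
            wts.append(1.0)
            labs.append(lab)
        elif n_est <= 2.6:
            # two beads merged into one blob: beads are Gaussian blobs, so
            # a two-Gaussian mixture fit recovers both centres; when they
            # are closer than ~1 px the joint centroid (the exact mean of
            # the two projections) is kept as a weight-2 marker instead
            t = np.radians(90.0 - orient)  # skimage orientation convention
            d0 = np.array([np.cos(t), np.sin(t)])
            init = [(h + d0[0], v + d0[1]), (h - d0[0], v - d0[1])]
            two = _fit_two_gaussians(
                img, labels_o, [lab], bbox, thr, sigma0, init
            )
            if two is not None:
                cents.extend(two)
                wts.extend([1.0, 1.0])
                labs.extend([lab, lab])
            else:
                cents.append((h, v))
                wts.append(2.0)
                labs.append(lab)
        # larger clusters are dropped (three-fold overlaps are hopeless
        # without the interactive corrections of a GUI tool)
    cents = np.array(cents) if cents else np.empty((0, 2))
    wts = np.array(wts) if len(wts) else np.empty(0)
    # a bead pair can also split into two touching components whose plain
    # centroids are cross-polluted; re-fit such close pairs jointly
    if len(cents) > 1:
        foot = 3.0 * np.sqrt(a1 / np.pi)
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        done = np.zeros(len(cents), bool)
        out_c, out_w = [], []
        for i in range(len(cents)):
            if done[i]:
                continue
            j = int(np.argmin(d[i]))
            if d[i, j] <= foot and not done[j] and wts[i] == wts[j] == 1 \
                    and labs[i] != labs[j]:
                bb = None
                for r in raw:
                    if r[5] in (labs[i], labs[j]):
                        b = r[6]
                        bb = b if bb is None else (
                            min(bb[0], b[0]), min(bb[1], b[1]),
                            max(bb[2], b[2]), max(bb[3], b[3]),
                        )
                two = _fit_two_gaussians(
                    img, labels_o, [labs[i], labs[j]], bb, thr, sigma0,
                    [tuple(cents[i]), tuple(cents[j])],
                )
                done[i] = done[j] = True
                if two is not None:
                    out_c.extend(two)
                    out_w.extend([1.0, 1.0])
                else:
                    out_c.append(0.5 * (cents[i] + cents[j]))
                    out_w.append(2.0)
            else:
                out_c.append(cents[i])
                out_w.append(wts[i])
                done[i] = True
        cents, wts = np.array(out_c), np.array(out_w)
    if overrides:
        for hv in overrides.get("remove", []):
            if len(cents):
                i = np.argmin(np.linalg.norm(cents - np.asarray(hv), axis=1))
                cents = np.delete(cents, i, axis=0)
                wts = np.delete(wts, i)
        add = overrides.get("add", [])
        if add:
            cents = np.vstack([cents, np.asarray(add, dtype=float)]) \
                if len(cents) else np.asarray(add, dtype=float)
            wts = np.concatenate([wts, np.ones(len(add))])
    return MarkerSet(cents, threshold=thr, weights=wts, sigma=sigma0)


# ---------------------------------------------------------------------------
# step 1b: ring classification
# ---------------------------------------------------------------------------

def classify_rings(markers: MarkerSet, image_center=None) -> MarkerSet:
    """Split centroids into upper/lower ring by their vertical positions.

    The split is placed at the largest gap in sorted v (restricted so each
    ring keeps >= 6 beads); ambiguous splits (overlapping rings) and
    collinear layouts raise with a hint to use segmentation overrides.
    """
    pts = markers.centroids
    wts = markers.weights
    if len(pts) < 10:
        raise CalibrationError(
            f"only {len(pts)} marker centroids detected; need at least 5 "
            "per ring to fit the ellipses"
        )
    # collinearity check
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise CalibrationError("marker centroids are collinear; cannot split rings")
    order = np.argsort(pts[:, 1])
    v = pts[order, 1]
    gaps = np.diff(v)
    n = len(pts)
    counts = np.arange(1, n)  # centroids below each candidate split
    valid = (counts >= 5) & (n - counts >= 5)
    if not valid.any():
        raise CalibrationError("cannot split rings with 5 markers each")
    k = int(np.flatnonzero(valid)[np.argmax(gaps[valid])])
    split_gap = gaps[k]
    others = np.delete(gaps, k)
    if len(others) and split_gap < 2.0 * np.median(others):
        raise CalibrationError(
            "ring split is ambiguous (rings overlap?); supply marker overrides"
        )
    labels = np.ones(len(pts), dtype=int)  # 1 = lower
    labels[order[k + 1 :]] = 0  # larger v = upper ring (world +z)
    return MarkerSet(
        pts, labels=labels, threshold=markers.threshold, weights=wts,
        sigma=markers.sigma,
    )


# ---------------------------------------------------------------------------
# step 2: ellipse pair
# ---------------------------------------------------------------------------

@dataclass
class EllipsePair:
    """Fitted conics of the two rings plus axis-line measurements (pixels).

    ``l1``/``l2`` are the inner gap and outer span between the two ellipses
    along the projected phantom axis; ``z_s`` the source distance derived
    from them (all in mm).  Converging points are filled in by the pitch and
    roll estimators; ``None`` encodes "at infinity" (zero inclination).
    """

    upper: EllipseFit
    lower: EllipseFit
    pixel_size: float = 1.0
    l1: float | None = None  # mm
    l2: float | None = None  # mm
    z_s: float | None = None  # mm
    p_theta: np.ndarray | None = None  # pitch converging point (h, v) px
    p_phi: np.ndarray | None = None  # roll converging point (h, v) px

    @property
    def axis_direction(self) -> np.ndarray:
        """Unit vector along the projected phantom axis (lower -> upper)."""
        d = self.upper.center - self.lower.center
        n = np.linalg.norm(d)
        if n < 1e-9:
            raise CalibrationError("coincident ellipse centres")
        return d / n

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.upper.center + self.lower.center)


def make_ellipse_pair(
    upper_pts: np.ndarray, lower_pts: np.ndarray, pixel_size: float = 1.0
) -> EllipsePair:
    return EllipsePair(
        upper=fit_ellipse(upper_pts),
        lower=fit_ellipse(lower_pts),
        pixel_size=pixel_size,
    )


def _axis_metrics(pair: EllipsePair, spec: CalibPhantomSpec):
    """Axis-line measurements in mm: L1 (inner gap), L2 (outer span), Z_S,
    and the axis extents of the two ellipses (equal iff pitch is zero)."""
    u = pair.axis_direction
    m = pair.midpoint
    tu = pair.upper.line_intersections(m, u)
    tl = pair.lower.line_intersections(m, u)
    if len(tu) < 2 or len(tl) < 2:
        raise CalibrationError("axis line does not cross both ellipses")
    px = pair.pixel_size
    l1 = (tu[0] - tl[1]) * px  # facing edges
    l2 = (tu[1] - tl[0]) * px  # far edges
    if l1 <= 0 or l2 <= 0:
        raise CalibrationError("ellipses overlap along the axis line")
    r = spec.radius
    h = spec.ring_separation
    denom = h * (l2 - l1)
    z_s = np.inf if denom == 0 else 2.0 * r * l1 * l2 / denom
    ext_u = (tu[1] - tu[0]) * px
    ext_l = (tl[1] - tl[0]) * px
    return float(l1), float(l2), float(z_s), float(ext_u), float(ext_l)


# ---------------------------------------------------------------------------
# steps 3-4: offsets and skew
# ---------------------------------------------------------------------------

def estimate_offsets_and_skew(
    pair: EllipsePair, detector: DetectorSpec
) -> tuple[float, float, float]:
    """Piercing-point offsets (pixels) and skew (degrees) of the detector.

    The piercing point is the midpoint of the two ellipse centres (exact for
    zero inclination, first-order otherwise); the skew is the tilt of the
    line joining the centres relative to the detector v axis.  Offsets
    follow the convention ``piercing_pixel = centre - offset``.
    """
    d = pair.upper.center - pair.lower.center
    if np.linalg.norm(d) < 1e-9:
        raise CalibrationError("coincident ellipse centres; skew undefined")
    eta = np.degrees(np.arctan2(d[0], d[1]))
    m = pair.midpoint
    offset_h = detector.center_h - m[0]
    offset_v = detector.center_v - m[1]
    return float(offset_h), float(offset_v), float(eta)


# ---------------------------------------------------------------------------
# step 5a: pitch
# ---------------------------------------------------------------------------

def estimate_pitch(
    pair: EllipsePair,
    spec: CalibPhantomSpec,
    phi: float = 0.0,
    piercing: np.ndarray | None = None,
) -> float:
    """Pitch angle (degrees) from the tangent-line converging point.

    ``pair`` must be measured in a de-skewed frame.  Fills ``pair.l1``,
    ``pair.l2``, ``pair.z_s`` and ``pair.p_theta`` as side products.
    """
    l1, l2, z_s, ext_u, ext_l = _axis_metrics(pair, spec)
    pair.l1, pair.l2, pair.z_s = l1, l2, z_s
    # zero-pitch degeneracy: both ellipses equally long along the axis
    # ("lengthier ellipse" criterion); the converging point is at infinity
    if abs(ext_u - ext_l) < PITCH_DEGENERACY_RTOL * 0.5 * (ext_u + ext_l):
        pair.p_theta = None
        return 0.0
    tang = common_tangents(pair.upper, pair.lower, outer_only=True)
    if len(tang) != 2:
        raise CalibrationError(
            f"expected 2 outer common tangents, found {len(tang)}"
        )
    try:
        p_theta = intersect_lines(tang[0], tang[1])
    except EllipseFitError:
        pair.p_theta = None  # parallel silhouette lines: zero pitch
        return 0.0
    pair.p_theta = p_theta
    ref = pair.midpoint if piercing is None else np.asarray(piercing, float)
    v_theta = (p_theta - ref) @ pair.axis_direction * pair.pixel_size
    if abs(v_theta) < 1e-9:
        raise CalibrationError("degenerate converging point at the piercing point")
    arg = z_s * np.cos(np.radians(phi)) / v_theta
    theta = np.degrees(np.arctan(arg))
    return float(theta)


# ---------------------------------------------------------------------------
# step 5b: roll
# ---------------------------------------------------------------------------

@dataclass
class RollCostParams:
    """Configuration and last evaluation of the roll convergence cost."""

    c1: float = 1.0  # weight, upper-ellipse term
    c2: float = 1.0  # weight, lower-ellipse term
    z_s_norm: float = float("nan")  # source distance used, normalized to px
    terms: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def cost(self) -> float:
        return float(self.c1 * self.terms[0] ** 2 + self.c2 * self.terms[1] ** 2)


def _angdiff(a: float, b: float) -> float:
    """Difference of two axis orientations (180-degree periodic), degrees."""
    d = (a - b + 90.0) % 180.0 - 90.0
    return d


def _pair_features(pair: EllipsePair):
    au, bu, angu = pair.upper.axes()
    al, bl, angl = pair.lower.axes()
    return np.array([angu, angl]), np.array([au, al]), np.array([bu, bl])


def _ellipse_feature_vec(pred: EllipseFit, meas: EllipseFit) -> np.ndarray:
    """Scale-normalized mismatch of one predicted vs measured ellipse."""
    a_m, b_m, ang_m = meas.axes()
    a_p, b_p, ang_p = pred.axes()
    dc = (pred.center - meas.center) / a_m
    aniso = 1.0 - b_m / a_m  # orientation is meaningless for circles
    return np.array(
        [
            dc[0],
            dc[1],
            (a_p - a_m) / a_m,
            (b_p - b_m) / b_m,
            np.radians(_angdiff(ang_p, ang_m)) * aniso,
        ]
    )


def roll_cost(
    phi: float,
    pair: EllipsePair,
    spec: CalibPhantomSpec,
    detector: DetectorSpec,
    theta: float,
    piercing_v: float,
    nuisance0: np.ndarray,
    params: RollCostParams | None = None,
    _warm: dict | None = None,
) -> float:
    """Convergence cost of the projected rings for a candidate roll.

    For the candidate ``phi`` the two ring conics are predicted by exact
    projection and compared with the measured pair (centres, semi-axes and
    — the roll-sensitive part — the long-axis orientations, whose
    convergence towards the roll converging point encodes phi).  The
    magnification-related nuisance parameters (piercing column, SOD, SDD)
    are profiled out by an inner least-squares solve so that the cost is a
    function of the roll alone; it is zero at the true roll on noise-free
    data.
    """
    if params is None:
        params = RollCostParams()
    if abs(phi) >= 85.0:
        return 1e6 + phi**2

    def resid(x):
        ph, sod, sdd = x
        if not (spec.radius * 1.2 < sod < 0.99 * sdd):
            return np.full(10, 1e3)
        try:
            pred = predict_ellipse_pair(
                spec, detector, 0.0, theta, phi, np.array([ph, piercing_v]),
                sod, sdd, n_samples=24,
            )
        except Exception:
            return np.full(10, 1e3)
        return np.concatenate(
            [
                _ellipse_feature_vec(pred.upper, pair.upper),
                _ellipse_feature_vec(pred.lower, pair.lower),
            ]
        )

    lb = np.array([-1e4, spec.radius * 1.25, 60.0])
    ub = np.array([1e4, 2e4, 4e4])
    x0 = np.asarray(nuisance0, dtype=float)
    if _warm is not None and "x" in _warm:
        x0 = _warm["x"]
    x0 = np.clip(x0, lb + 1e-6, ub - 1e-6)
    if x0[1] >= 0.98 * x0[2]:
        x0[1] = 0.5 * x0[2]
    res = least_squares(
        resid, x0, method="trf", bounds=(lb, ub),
        x_scale=[10, 100, 100], xtol=1e-10, ftol=1e-10, max_nfev=30,
    )
    if _warm is not None:
        _warm["x"] = res.x
    r = res.fun
    params.terms = np.array(
        [np.linalg.norm(r[:5]), np.linalg.norm(r[5:])]
    )
    params.z_s_norm = res.x[2] / detector.pixel_size
    return params.cost()


def estimate_roll(
    pair: EllipsePair,
    z_s: float,
    spec: CalibPhantomSpec,
    detector: DetectorSpec,
    theta: float = 0.0,
    sod: float | None = None,
    piercing_px: np.ndarray | None = None,
    params: RollCostParams | None = None,
    multistart=(-45.0, 0.0, 45.0),
) -> tuple[float, float]:
    """Roll angle by Nelder-Mead minimization of the convergence cost.

    The apparent ring size depends on both the magnification and the roll,
    so the magnification nuisances (piercing column, SOD, SDD) are profiled
    out inside the cost.  Multi-start simplex; returns
    ``(phi, cost_at_optimum)``.
    """
    sdd = z_s * np.cos(np.radians(theta))
    if piercing_px is None:
        piercing_px = pair.midpoint
    if sod is None:
        _, a_m, _ = _pair_features(pair)
        a_mm = float(np.mean(a_m)) * pair.pixel_size
        sod = spec.radius * np.sqrt(1.0 + (sdd / a_mm) ** 2)
    nuis0 = np.array([piercing_px[0], sod, sdd])
    piercing_v = float(piercing_px[1])

    best = None
    for phi0 in multistart:
        warm = {}

        def cost1d(x):
            return roll_cost(
                float(x[0]), pair, spec, detector, theta, piercing_v,
                nuis0, params=params, _warm=warm,
            )

        res = minimize(
            cost1d,
            x0=[phi0],
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-14, "maxfev": 100},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise CalibrationError("roll optimization failed to converge")
    phi = float(best.x[0])
    # record the converging point of the long axes when it exists
    try:
        pair.p_phi = _axes_intersection(pair)
    except Exception:
        pair.p_phi = None
    return phi, float(best.fun)


def _axes_intersection(pair: EllipsePair) -> np.ndarray:
    lines = []
    for e in (pair.upper, pair.lower):
        _, _, ang = e.axes()
        t = np.radians(ang)
        d = np.array([np.cos(t), np.sin(t)])
        n = np.array([-d[1], d[0]])
        lines.append((n, float(n @ e.center)))
    return intersect_lines(*lines)


# ---------------------------------------------------------------------------
# analytic forward model: geometry -> ellipse pair
# ---------------------------------------------------------------------------

def _geometry_from_params(
    detector: DetectorSpec,
    eta: float,
    theta: float,
    phi: float,
    piercing_px: np.ndarray,
    sod: float,
    sdd: float,
    angle: float = 0.0,
) -> ViewGeometry:
    offset_h = detector.center_h - piercing_px[0]
    offset_v = detector.center_v - piercing_px[1]
    return make_view_geometry(
        angle, sdd, sod, detector,
        skew=eta, pitch=theta, roll=phi,
        offset_h=offset_h, offset_v=offset_v,
    )


def predict_ellipse_pair(
    spec: CalibPhantomSpec,
    detector: DetectorSpec,
    eta: float,
    theta: float,
    phi: float,
    piercing_px: np.ndarray,
    sod: float,
    sdd: float,
    n_samples: int = 64,
) -> EllipsePair:
    """Exact projected conics of the two rings for a candidate geometry.

    The full rings (not just the beads) are projected: the image of a circle
    is an exact conic, so fitting the projected samples recovers it to
    rounding error.  This is the internal forward model used by the roll
    cost and the final polish.
    """
    g = _geometry_from_params(detector, eta, theta, phi, piercing_px, sod, sdd)
    az = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    r, hh = spec.radius, spec.ring_separation / 2.0
    ring = np.column_stack([r * np.cos(az), r * np.sin(az)])
    pts_u = np.column_stack([ring, np.full(n_samples, hh)])
    pts_l = np.column_stack([ring, np.full(n_samples, -hh)])
    up = project_points(g, detector, pts_u)
    lo = project_points(g, detector, pts_l)
    return EllipsePair(
        upper=fit_ellipse(up), lower=fit_ellipse(lo),
        pixel_size=detector.pixel_size,
    )


# ---------------------------------------------------------------------------
# step 6: source and detector positions
# ---------------------------------------------------------------------------

def estimate_source_detector(
    pair: EllipsePair,
    spec: CalibPhantomSpec,
    detector: DetectorSpec,
    offsets: tuple[float, float],
    eta: float,
    theta: float,
    phi: float,
    angle: float = 0.0,
) -> ViewGeometry:
    """Assemble the full per-view geometry from the estimated parameters.

    SDD follows from the axis-line source distance (``Z_S cos(theta)``); the
    source-to-object distance from the projected ring size,
    ``SOD = R sqrt(1 + (SDD/a_mm)^2)`` with ``a_mm`` the mean semi-major
    axis in mm.
    """
    if pair.z_s is None:
        pair.z_s = _axis_metrics(pair, spec)[2]
    sdd = pair.z_s * np.cos(np.radians(theta))
    if not np.isfinite(sdd) or sdd <= 0:
        raise CalibrationError("inconsistent source distance estimate")
    a_u, _, _ = pair.upper.axes()
    a_l, _, _ = pair.lower.axes()
    a_mm = 0.5 * (a_u + a_l) * pair.pixel_size
    sod = spec.radius * np.sqrt(1.0 + (sdd / a_mm) ** 2)
    return make_view_geometry(
        angle, sdd, sod, detector,
        skew=eta, pitch=theta, roll=phi,
        offset_h=offsets[0], offset_v=offsets[1],
    )


# ---------------------------------------------------------------------------
# full per-view calibration
# ---------------------------------------------------------------------------

def _conic_residual_features(pair: EllipsePair) -> np.ndarray:
    """Smooth 5-vector per ellipse: centre plus scaled inverse shape matrix."""
    out = []
    for e in (pair.upper, pair.lower):
        W = np.linalg.inv(e.shape_matrix)  # px^2, no angle wrap
        s = np.sqrt(max(W[0, 0] + W[1, 1], 1e-12))
        out.extend([e.h0, e.v0, W[0, 0] / s, W[1, 1] / s, W[0, 1] / s])
    return np.array(out)


def _rotate_pts(pts, center, deg):
    t = np.radians(deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return (pts - center) @ R.T + center


def calibrate_view(
    img_or_markers,
    spec: CalibPhantomSpec,
    detector: DetectorSpec,
    angle: float = 0.0,
    threshold: float | None = None,
    overrides: dict | None = None,
    max_alternations: int = 3,
    alternation_tol: float = 0.01,
    polish: bool = True,
    init_geometry: ViewGeometry | None = None,
    fix_sod_sdd: tuple[float, float] | None = None,
    max_reprojection_rms: float = 1.0,
) -> tuple[ViewGeometry, dict]:
    """Run the six calibration steps (plus polish) on one projection.

    Accepts either a raw 2-D projection image or a pre-classified
    :class:`MarkerSet`.  Returns the per-view geometry and a quality report
    (marker count, fit residuals, polish residual norm).  When
    ``init_geometry`` is given (e.g. the calibrated neighbour of a view with
    too many overlapping markers) the ellipse stages are skipped and the
    bead-reprojection fit runs directly from that starting geometry.
    """
    if isinstance(img_or_markers, MarkerSet):
        markers = img_or_markers
    else:
        markers = segment_markers(img_or_markers, threshold, overrides)
    if init_geometry is not None:
        if not polish:
            raise ValueError("init_geometry requires the polish stage")
        if markers.n_beads < 8:
            raise CalibrationError(
                f"only {markers.n_beads} beads detected; too few to refit"
            )
        geoms = (
            list(init_geometry)
            if isinstance(init_geometry, (list, tuple))
            else [init_geometry]
        )
        geom, rms, xfit = _bead_polish(
            markers, spec, detector, geoms[0], angle,
            extra_geoms=geoms[1:], fix_sod_sdd=fix_sod_sdd,
        )
        geom, rms = _remeasure_and_refit(
            img_or_markers, markers, spec, detector, geom, xfit, angle,
            fix_sod_sdd, rms,
        )
        if rms > max_reprojection_rms:
            raise CalibrationError(
                f"bead reprojection rms {rms:.2f} px exceeds "
                f"{max_reprojection_rms} px"
            )
        return geom, {
            "n_markers": len(markers),
            "fit_residual_upper": float("nan"),
            "fit_residual_lower": float("nan"),
            "polish_residual": float("nan"),
            "reprojection_rms": rms,
        }
    if markers.labels is None:
        markers = classify_rings(markers)
    up_pts = markers.ring("upper")
    lo_pts = markers.ring("lower")
    if len(up_pts) < 5 or len(lo_pts) < 5:
        raise CalibrationError("too few markers for the ellipse stage")
    pair = make_ellipse_pair(up_pts, lo_pts, detector.pixel_size)

    offset_h, offset_v, eta = estimate_offsets_and_skew(pair, detector)
    piercing = pair.midpoint.copy()
    theta, phi = 0.0, 0.0
    roll_params = RollCostParams()
    sod = None
    for it in range(max_alternations):
        # de-skewed frame: rotate centroids about the piercing estimate
        up_d = _rotate_pts(up_pts, piercing, -eta)
        lo_d = _rotate_pts(lo_pts, piercing, -eta)
        pair_d = make_ellipse_pair(up_d, lo_d, detector.pixel_size)
        theta_new = estimate_pitch(pair_d, spec, phi=phi, piercing=piercing)
        phi_new, _ = estimate_roll(
            pair_d, pair_d.z_s, spec, detector,
            theta=theta_new, piercing_px=piercing, params=roll_params,
            multistart=(0.0,) if it == 0 else (phi,),
        )
        done = abs(theta_new - theta) < alternation_tol and \
            abs(phi_new - phi) < alternation_tol
        theta, phi = theta_new, phi_new
        pair.l1, pair.l2, pair.z_s = pair_d.l1, pair_d.l2, pair_d.z_s
        pair.p_theta, pair.p_phi = pair_d.p_theta, pair_d.p_phi
        if done:
            break
        # correct skew/piercing for the tilt-induced slant of the centre line
        try:
            sdd_c = pair.z_s * np.cos(np.radians(theta))
            a_mm = 0.5 * sum(e.axes()[0] for e in (pair_d.upper, pair_d.lower)) \
                * detector.pixel_size
            sod_c = spec.radius * np.sqrt(1.0 + (sdd_c / a_mm) ** 2)
            pred = predict_ellipse_pair(
                spec, detector, 0.0, theta, phi,
                np.array([detector.center_h, detector.center_v]), sod_c, sdd_c,
            )
            d_p = pred.upper.center - pred.lower.center
            slant = np.degrees(np.arctan2(d_p[0], d_p[1]))
            bias = pred.midpoint - np.array(
                [detector.center_h, detector.center_v]
            )
            d_m = pair.upper.center - pair.lower.center
            eta = np.degrees(np.arctan2(d_m[0], d_m[1])) - slant
            piercing = pair.midpoint - _rotate_pts(
                bias[None, :], np.zeros(2), eta
            )[0]
            sod = sod_c
        except Exception:
            pass
    offset_h = detector.center_h - piercing[0]
    offset_v = detector.center_v - piercing[1]
    geom = estimate_source_detector(
        pair, spec, detector, (offset_h, offset_v), eta, theta, phi, angle
    )
    quality = {
        "n_markers": len(markers),
        "fit_residual_upper": pair.upper.residual,
        "fit_residual_lower": pair.lower.residual,
        "polish_residual": float("nan"),
        "reprojection_rms": float("nan"),
    }
    if polish:
        geom, pres = _polish_view(pair, spec, detector, geom, angle)
        quality["polish_residual"] = pres
        geom, rms, xfit = _bead_polish(
            markers, spec, detector, geom, angle, fix_sod_sdd=fix_sod_sdd
        )
        geom, rms = _remeasure_and_refit(
            img_or_markers, markers, spec, detector, geom, xfit, angle,
            fix_sod_sdd, rms,
        )
        quality["reprojection_rms"] = rms
        if rms > max_reprojection_rms:
            raise CalibrationError(
                f"bead reprojection rms {rms:.2f} px exceeds "
                f"{max_reprojection_rms} px"
            )
    return geom, quality


def _remeasure_and_refit(img_or_markers, markers, spec, detector, geom,
                         xfit, angle, fix_sod_sdd, rms0):
    """Second measurement pass: re-extract every bead centroid with a
    model-driven mixture fit at the predicted positions, then refit the
    geometry once more.  Skipped when only a MarkerSet (no image) is
    available; keeps the first fit when it does not improve."""
    if isinstance(img_or_markers, MarkerSet):
        return geom, rms0
    img = np.asarray(img_or_markers, dtype=float)
    try:
        up, lo = _predict_beads(spec, detector, xfit, angle=0.0)
        pred = np.vstack([up, lo])
        sigma0 = markers.sigma if np.isfinite(markers.sigma) else 1.0
        mk2 = _remeasure_markers(img, markers.threshold, pred, sigma0)
        if len(mk2) < max(10, len(markers)):
            return geom, rms0
        geom2, rms2, _ = _bead_polish(mk2, spec, detector, geom, angle,
                                      fix_sod_sdd=fix_sod_sdd)
        if rms2 < rms0:
            return geom2, rms2
    except Exception:
        pass
    return geom, rms0


def _polish_view(pair, spec, detector, geom0, angle):
    """Bounded LS refinement of all 7 per-view parameters against the
    measured conics, with structured restarts (pitch/roll sign flips) in
    case the staged initialization landed in the wrong basin."""
    meas = _conic_residual_features(pair)
    sod0 = float(np.linalg.norm(geom0.source_pos))
    piercing0 = np.array(
        [
            detector.center_h - geom0.offset_h,
            detector.center_v - geom0.offset_v,
        ]
    )

    def resid(x):
        eta, theta, phi, ph, pv, sod, sdd = x
        if abs(theta) >= 85 or abs(phi) >= 85 or abs(eta) >= 85:
            return np.full_like(meas, 1e3)
        if not (spec.radius * 1.1 < sod < sdd):
            return np.full_like(meas, 1e3)
        try:
            pred = predict_ellipse_pair(
                spec, detector, eta, theta, phi, np.array([ph, pv]), sod, sdd
            )
        except Exception:
            return np.full_like(meas, 1e3)
        return _conic_residual_features(pred) - meas

    ext = max(detector.width_mm, detector.height_mm) / detector.pixel_size
    lb = np.array([-80, -80, -80, -2 * ext, -2 * ext, spec.radius * 1.2, 50.0])
    ub = np.array([80, 80, 80, 3 * ext, 3 * ext, 2e4, 4e4])
    base = np.array(
        [geom0.skew, geom0.pitch, geom0.roll,
         piercing0[0], piercing0[1], sod0, geom0.sdd]
    )
    starts = [base]
    for st, sp in ((1, -1), (-1, 1), (-1, -1)):
        alt = base.copy()
        alt[1] *= st
        alt[2] *= sp
        starts.append(alt)
    best = None
    good_enough = 1e-6 * max(np.linalg.norm(meas), 1.0)
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-6, ub - 1e-6)
        res = least_squares(
            resid, x0, method="trf", bounds=(lb, ub),
            x_scale=[1, 1, 1, 10, 10, 100, 100],
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
        )
        if best is None or res.cost < best.cost:
            best = res
        if np.linalg.norm(best.fun) < good_enough:
            break
    eta, theta, phi, ph, pv, sod, sdd = best.x
    g = make_view_geometry(
        angle, sdd, sod, detector,
        skew=eta, pitch=theta, roll=phi,
        offset_h=detector.center_h - ph, offset_v=detector.center_v - pv,
    )
    return g, float(np.linalg.norm(best.fun))


def _predict_beads(spec, detector, x, angle=0.0):
    """Predicted bead pixel positions (upper, lower) for parameter vector
    ``x = (eta, theta, phi, piercing_h, piercing_v, sod, sdd, azimuth)``."""
    eta, theta, phi, ph, pv, sod, sdd, az = x
    g = _geometry_from_params(
        detector, eta, theta, phi, np.array([ph, pv]), sod, sdd, angle
    )
    nb = spec.beads_per_ring
    azs = np.deg2rad(az + 360.0 * np.arange(nb) / nb)
    r, hh = spec.radius, spec.ring_separation / 2.0
    ring = np.column_stack([r * np.cos(azs), r * np.sin(azs)])
    up = np.column_stack([ring, np.full(nb, hh)])
    lo = np.column_stack([ring, np.full(nb, -hh)])
    return project_points(g, detector, up), project_points(g, detector, lo)


def _remeasure_markers(img, threshold, pred, sigma0):
    """Model-driven marker re-measurement.

    Given predicted bead positions from a first geometry estimate, clusters
    of nearby predictions are re-fit jointly as K-Gaussian mixtures on the
    raw image, which resolves arbitrarily overlapping beads without any
    blob-counting heuristics.  Returns a MarkerSet of the re-fitted
    centroids (failed clusters are simply omitted).
    """
    n_v, n_h = img.shape
    pred = np.asarray(pred)
    ok = (
        (pred[:, 0] > 2) & (pred[:, 0] < n_h - 3)
        & (pred[:, 1] > 2) & (pred[:, 1] < n_v - 3)
    )
    pred = pred[ok]
    # single-linkage clustering with a 6 px threshold
    n = len(pred)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pred[i] - pred[j]) < 6.0:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    cents = []
    for idx in clusters.values():
        pts = pred[idx]
        k = len(pts)
        h0 = int(np.floor(pts[:, 0].min())) - 4
        h1 = int(np.ceil(pts[:, 0].max())) + 5
        v0 = int(np.floor(pts[:, 1].min())) - 4
        v1 = int(np.ceil(pts[:, 1].max())) + 5
        h0, v0 = max(h0, 0), max(v0, 0)
        h1, v1 = min(h1, n_h), min(v1, n_v)
        win = img[v0:v1, h0:h1]
        hh, vv = np.meshgrid(np.arange(h0, h1), np.arange(v0, v1))
        amp0 = float(win.max())
        if amp0 <= 0:
            continue

        def model(x):
            out = -win
            for m in range(k):
                a = x[m]
                cx, cy = x[k + 2 * m], x[k + 2 * m + 1]
                out = out + a * np.exp(
                    -((hh - cx) ** 2 + (vv - cy) ** 2) / (2 * x[-1] ** 2)
                )
            return out.ravel()

        x0 = np.concatenate(
            [np.full(k, amp0), pts.ravel(), [max(sigma0, 0.5)]]
        )
        try:
            res = least_squares(
                model, x0, method="lm", xtol=1e-10, ftol=1e-10,
                max_nfev=120 * (k + 1),
            )
        except Exception:
            continue
        rel = np.linalg.norm(res.fun) / max(np.linalg.norm(win), 1e-9)
        if rel > 0.15:
            continue
        good = True
        fitted = []
        for m in range(k):
            c = res.x[k + 2 * m : k + 2 * m + 2]
            if np.linalg.norm(c - pts[m]) > 3.0 or res.x[m] < 0.15 * amp0:
                good = False
                break
            fitted.append((float(c[0]), float(c[1])))
        if good:
            cents.extend(fitted)
    if not cents:
        return MarkerSet(np.empty((0, 2)), threshold=threshold)
    return MarkerSet(np.array(cents), threshold=threshold)


def _bead_polish(markers: MarkerSet, spec, detector, geom0, angle,
                 extra_geoms=(), fix_sod_sdd=None):
    """Final bead-reprojection least squares over all view parameters plus
    the apparent phantom azimuth.

    The conic-feature stages compress the centroids into 10 ellipse
    numbers; re-fitting against the individual bead positions restores the
    full statistical strength of the measurements (up to 32 observations
    for 8 parameters) and is what makes the calibration robust to the
    sub-0.1 px centroid noise of real segmentations.  The correspondence is
    merged-aware: every predicted bead claims its nearest measured
    centroid, and predicted beads sharing a weight-2 centroid (two beads
    projecting on top of each other) are compared through their mean — so
    overlapping markers contribute without bias instead of being lost.
    """
    def as_x(g):
        return np.array(
            [
                g.skew, g.pitch, g.roll,
                detector.center_h - g.offset_h,
                detector.center_v - g.offset_v,
                float(np.linalg.norm(g.source_pos)), g.sdd, 0.0,
            ]
        )

    bases = [as_x(geom0)] + [as_x(g) for g in extra_geoms]
    meas = markers.centroids
    wts = markers.weights
    nb = spec.beads_per_ring
    n_pred = 2 * nb
    n_out = max(2 * n_pred, 2 * len(meas))

    def predict_all(x):
        up, lo = _predict_beads(spec, detector, x)
        return np.vstack([up, lo])

    def _diffs(pred):
        """Per-measured-centroid residuals.  A weight-1 centroid is
        compared with its nearest predicted bead; a weight-2 centroid (two
        beads projecting on top of each other) with the mean of its two
        nearest predicted beads — which is exactly what its centre of mass
        measures."""
        d = np.linalg.norm(meas[:, None, :] - pred[None, :, :], axis=2)
        out = np.zeros((len(meas), 2))
        for jm in range(len(meas)):
            order = np.argsort(d[jm])
            # the weight-2 hint is honoured only when a second predicted
            # bead is actually nearby (an oversized single blob can be
            # mis-flagged as a merged pair by the area test)
            k = 2 if (wts[jm] >= 2 and d[jm, order[1]] < 5.0) else 1
            sel = order[:k]
            out[jm] = meas[jm] - pred[sel].mean(axis=0)
        return out

    def match_cost(x):
        try:
            pred = predict_all(x)
        except Exception:
            return np.inf
        return float(np.linalg.norm(_diffs(pred), axis=1).sum())

    def resid(x):
        if abs(x[1]) >= 85 or abs(x[2]) >= 85 or abs(x[0]) >= 85:
            return np.full(n_out, 1e3)
        if not (spec.radius * 1.1 < x[5] < x[6]):
            return np.full(n_out, 1e3)
        try:
            pred = predict_all(x)
        except Exception:
            return np.full(n_out, 1e3)
        out = np.zeros(n_out)
        r = _diffs(pred).ravel()
        out[: len(r)] = r
        return out

    ext = max(detector.width_mm, detector.height_mm) / detector.pixel_size
    lb = np.array(
        [-80, -80, -80, -2 * ext, -2 * ext, spec.radius * 1.2, 50.0, -360]
    )
    ub = np.array([80, 80, 80, 3 * ext, 3 * ext, 2e4, 4e4, 360])
    if fix_sod_sdd is not None:
        # scan-level consistency: SOD/SDD are mechanical constants of the
        # scan; pinning them removes two weakly determined directions from
        # views with many overlapping markers
        sod_f, sdd_f = fix_sod_sdd
        lb[5], ub[5] = sod_f - 1e-6, sod_f + 1e-6
        lb[6], ub[6] = sdd_f - 1e-6, sdd_f + 1e-6
        for b in bases:
            b[5], b[6] = sod_f, sdd_f
    # the bead phase is 360/nb-periodic; scan one period for the start,
    # and restart from pitch/roll sign flips in case the staged init
    # picked the mirrored basin
    period = 360.0 / nb
    azs = np.arange(0.0, period, period / 32.0)
    starts = []
    for base in bases:
        for st, sp in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            cand = base.copy()
            cand[1] *= st
            cand[2] *= sp
            if any(
                np.allclose(cand[:7], s[:7], atol=1e-9) for s in starts
            ):
                continue
            costs = []
            for az in azs:
                x = cand.copy()
                x[7] = az
                costs.append(match_cost(x))
            cand[7] = azs[int(np.argmin(costs))]
            starts.append(cand)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-6, ub - 1e-6)
        res = least_squares(
            resid, x0, method="trf", bounds=(lb, ub),
            x_scale=[1, 1, 1, 10, 10, 100, 100, 1],
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300,
        )
        if best is None or res.cost < best.cost:
            best = res
        if np.sqrt(2 * best.cost / max(len(meas), 1)) < 0.08:
            break
    res = best
    eta, theta, phi, ph, pv, sod, sdd, _ = res.x
    g = make_view_geometry(
        angle, sdd, sod, detector,
        skew=eta, pitch=theta, roll=phi,
        offset_h=detector.center_h - ph, offset_v=detector.center_v - pv,
    )
    rms = float(np.sqrt(np.sum(res.fun**2) / max(len(meas), 1)))
    return g, rms, res.x.copy()


def calibrate_scan(
    projections: ProjectionSet,
    spec: CalibPhantomSpec,
    threshold: float | None = None,
    max_failure_fraction: float = 0.2,
    polish: bool = True,
) -> tuple[Trajectory, list[dict]]:
    """Per-view calibration of a whole phantom scan.

    Views that fail (blank frame, too few markers, degenerate fits) are
    flagged in the report and carried over with their nominal geometry; the
    scan as a whole fails when more than ``max_failure_fraction`` of views do.
    """
    traj = projections.trajectory
    det = projections.detector
    out_views, report = [], []
    for i, g in enumerate(traj):
        rec = {"view": i, "angle": g.angle, "ok": True, "error": ""}
        try:
            geom, quality = calibrate_view(
                projections.data[i], spec, det, angle=g.angle,
                threshold=threshold, polish=polish,
            )
            rec.update(quality)
        except (CalibrationError, EllipseFitError) as exc:
            rec["ok"] = False
            rec["error"] = f"view {i} (angle {g.angle:.1f}): {exc}"
            geom = g.copy()
        out_views.append(geom)
        report.append(rec)
    # second pass: views with too many overlapping markers for the ellipse
    # stage are refit directly from the nearest calibrated neighbour; if
    # that is still under-determined, SOD/SDD are pinned to the scan
    # medians (they are mechanical constants of the scan)
    ok_idx = [i for i, r in enumerate(report) if r["ok"]]
    if polish and ok_idx:
        med_sod = float(
            np.median([np.linalg.norm(out_views[k].source_pos) for k in ok_idx])
        )
        med_sdd = float(np.median([out_views[k].sdd for k in ok_idx]))
        for i, rec in enumerate(report):
            if rec["ok"]:
                continue
            j = min(ok_idx, key=lambda k: abs(k - i))
            nb_g = out_views[j]
            ang = traj.views[i].angle
            sod_n = float(np.linalg.norm(nb_g.source_pos))
            inits = [
                make_view_geometry(
                    ang, nb_g.sdd, sod_n, det,
                    skew=nb_g.skew, pitch=nb_g.pitch, roll=nb_g.roll,
                    offset_h=nb_g.offset_h, offset_v=nb_g.offset_v,
                ),
                make_view_geometry(ang, nb_g.sdd, sod_n, det),
                make_view_geometry(
                    ang, nb_g.sdd, sod_n, det, pitch=10.0, roll=10.0
                ),
                make_view_geometry(ang, nb_g.sdd, sod_n, det, pitch=10.0),
                make_view_geometry(ang, nb_g.sdd, sod_n, det, roll=10.0),
                make_view_geometry(
                    ang, nb_g.sdd, sod_n, det, pitch=5.0, roll=5.0
                ),
            ]
            recovered = False
            for fix in (None, (med_sod, med_sdd)):
                try:
                    geom, quality = calibrate_view(
                        projections.data[i], spec, det,
                        angle=ang, threshold=threshold,
                        init_geometry=inits, fix_sod_sdd=fix,
                        max_reprojection_rms=0.5,
                    )
                    out_views[i] = geom
                    rec.update(quality)
                    rec["ok"] = True
                    rec["error"] += " [recovered from neighbour init]"
                    recovered = True
                    break
                except (CalibrationError, EllipseFitError) as exc:
                    last_exc = exc
            if not recovered:
                rec["error"] += f"; retry failed: {last_exc}"
    n_fail = sum(not r["ok"] for r in report)
    for r in report:
        if not r["ok"]:
            warnings.warn(r["error"])
    if n_fail > max_failure_fraction * len(traj):
        raise CalibrationError(
            f"{n_fail}/{len(traj)} views failed calibration"
        )
    return Trajectory(out_views, det, traj.angular_span), report
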