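"""Conic (ellipse) fitting and projective helpers for the BB-ring images.

A projected marker ring is an ellipse.  Two equivalent parameterizations are
kept: the centred quadratic form

    a (h - h0)^2 + b (v - v0)^2 + 2 c (h - h0)(v - v0) = 1

and the polynomial form

    p0 h^2 + v^2 - 2 p1 h - 2 p2 v + 2 p3 h v + p4 = 0

fitted linearly to the marker centroids; the conversion between the two is
the standard relation for central conics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["EllipseFit", "fit_ellipse", "ellipse_points", "common_tangents"]


class EllipseFitError(ValueError):
    """Degenerate marker configuration: no unique ellipse through the points."""


@dataclass
class EllipseFit:
    """Least-squares conic through a set of marker centroids (pixel units)."""

    h0: float
    v0: float
    a: float
    b: float
    c: float
    p: np.ndarray  # (p0..p4)
    residual: float  # rms of the normalized quadratic form minus 1
    n_points: int

    # -- derived shape ----------------------------------------------------
    @property
    def shape_matrix(self) -> np.ndarray:
        return np.array([[self.a, self.c], [self.c, self.b]])

    @property
    def center(self) -> np.ndarray:
        return np.array([self.h0, self.v0])

    def axes(self) -> tuple[float, float, float]:
        """(semi_major, semi_minor, major_axis_angle_deg).

        The angle is measured from the +h axis toward +v, in (-90, 90].
        """
        w, vecs = np.linalg.eigh(self.shape_matrix)
        # eigh sorts ascending: w[0] -> major axis (largest 1/sqrt)
        semi_major = 1.0 / np.sqrt(w[0])
        semi_minor = 1.0 / np.sqrt(w[1])
        vec = vecs[:, 0]
        ang = np.degrees(np.arctan2(vec[1], vec[0]))
        if ang <= -90.0:
            ang += 180.0
        elif ang > 90.0:
            ang -= 180.0
        return semi_major, semi_minor, ang

    def value(self, h, v) -> np.ndarray:
        """Quadratic form (=1 on the ellipse)."""
        dh = np.asarray(h) - self.h0
        dv = np.asarray(v) - self.v0
        return self.a * dh**2 + self.b * dv**2 + 2 * self.c * dh * dv

    def line_intersections(self, point, direction) -> np.ndarray:
        """Parameters t of the intersections of ``point + t*direction``.

        Returns the (sorted) real roots; empty if the line misses.
        """
        p = np.asarray(point, dtype=float) - self.center
        d = np.asarray(direction, dtype=float)
        M = self.shape_matrix
        A = d @ M @ d
        B = 2 * (p @ M @ d)
        C = p @ M @ p - 1.0
        disc = B * B - 4 * A * C
        if disc < 0 or A == 0:
            return np.array([])
        sq = np.sqrt(disc)
        return np.sort(np.array([(-B - sq) / (2 * A), (-B + sq) / (2 * A)]))


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Fit a conic to >=5 centroids (columns h, v) and convert to Eq-1 form.

    Raises :class:`EllipseFitError` when the system is rank deficient or the
    conic is not an ellipse (points collinear, circle-degenerate layouts).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise EllipseFitError("need at least 5 (h, v) points")
    h, v = pts[:, 0], pts[:, 1]
    # precondition: work in centred/scaled coordinates, map p back after
    mh, mv = h.mean(), v.mean()
    s = max(np.std(h), np.std(v), 1e-12)
    hs, vs = (h - mh) / s, (v - mv) / s
    A = np.column_stack([hs**2, -2 * hs, -2 * vs, 2 * hs * vs, np.ones_like(hs)])
    rhs = -(vs**2)
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 5:
        raise EllipseFitError("rank-deficient marker configuration")
    p0, p1, p2, p3, p4 = sol
    den = p0 - p3**2
    if abs(den) < 1e-12:
        raise EllipseFitError("degenerate conic (parabolic)")
    h0s = (p1 - p2 * p3) / den
    v0s = (p0 * p2 - p1 * p3) / den
    dd = p0 * h0s**2 + v0s**2 + 2 * p3 * h0s * v0s - p4
    if abs(dd) < 1e-15:
        raise EllipseFitError("degenerate conic (point ellipse)")
    a_s = p0 / dd
    b_s = 1.0 / dd
    c_s = p3 / dd
    if not (a_s > 0 and b_s > 0 and a_s * b_s - c_s**2 > 0):
        raise EllipseFitError("fitted conic is not an ellipse")
    # un-scale: (h - h0)/s etc.  => a -> a/s^2
    h0 = h0s * s + mh
    v0 = v0s * s + mv
    a, b, c = a_s / s**2, b_s / s**2, c_s / s**2
    # polynomial coefficients in the original frame (for reporting/tests)
    p_orig = _poly_from_centered(h0, v0, a, b, c)
    vals = a * (h - h0) ** 2 + b * (v - v0) ** 2 + 2 * c * (h - h0) * (v - v0)
    return EllipseFit(
        h0=float(h0),
        v0=float(v0),
        a=float(a),
        b=float(b),
        c=float(c),
        p=p_orig,
        residual=float(np.sqrt(np.mean((vals - 1.0) ** 2))),
        n_points=len(pts),
    )


def _poly_from_centered(h0, v0, a, b, c) -> np.ndarray:
    """Normalize the centred form back to (p0..p4) with the v^2 term = 1."""
    # a dh^2 + b dv^2 + 2c dh dv - 1 = 0, divide by b
    p0 = a / b
    p3 = c / b
    p1 = p0 * h0 + p3 * v0
    p2 = v0 + p3 * h0
    p4 = p0 * h0**2 + v0**2 + 2 * p3 * h0 * v0 - 1.0 / b
    return np.array([p0, p1, p2, p3, p4])


def ellipse_points(fit: EllipseFit, n: int = 64) -> np.ndarray:
    """Exact points on the fitted ellipse (for plotting / round trips)."""
    w, vecs = np.linalg.eigh(fit.shape_matrix)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    circ = np.column_stack([np.cos(t) / np.sqrt(w[0]), np.sin(t) / np.sqrt(w[1])])
    return fit.center + circ @ vecs.T


def _tangent_line(fit: EllipseFit, t: float):
    """Tangent line (n, d) with n.x = d at boundary parameter t."""
    w, vecs = np.linalg.eigh(fit.shape_matrix)
    x = fit.center + vecs @ np.array(
        [np.cos(t) / np.sqrt(w[0]), np.sin(t) / np.sqrt(w[1])]
    )
    n = fit.shape_matrix @ (x - fit.center)
    return n, float(n @ x)


def common_tangents(e1: EllipseFit, e2: EllipseFit, outer_only: bool = True):
    """Common tangent lines of two non-overlapping ellipses.

    Lines are returned as ``(n, d)`` with ``n . x = d``.  Outer tangents are
    those leaving both ellipse centres on the same side (the silhouette
    lines of the BB cylinder).
    """
    Minv2 = np.linalg.inv(e2.shape_matrix)

    def g(t):
        n, d = _tangent_line(e1, t)
        miss = n @ e2.center - d
        return miss * miss - n @ Minv2 @ n

    ts = np.linspace(0, 2 * np.pi, 241)
    vals = np.array([g(t) for t in ts])
    lines = []
    for i in range(len(ts) - 1):
        if vals[i] == 0.0:
            root = ts[i]
        elif vals[i] * vals[i + 1] < 0:
            root = brentq(g, ts[i], ts[i + 1], xtol=1e-12)
        else:
            continue
        n, d = _tangent_line(e1, root)
        if outer_only and (n @ e2.center - d) > 0:
            continue  # e2 on the opposite side of e1 (crossing tangent)
        nrm = np.linalg.norm(n)
        lines.append((n / nrm, d / nrm))
    # deduplicate nearly identical lines from adjacent brackets
    uniq = []
    for n, d in lines:
        dup = any(
            np.allclose(n, n2, atol=1e-8) and abs(d - d2) < 1e-6
            for n2, d2 in uniq
        )
        if not dup:
            uniq.append((n, d))
    return uniq


def intersect_lines(l1, l2) -> np.ndarray:
    """Intersection point of two (n, d) lines; raises if parallel."""
    A = np.vstack([l1[0], l2[0]])
    b = np.array([l1[1], l2[1]])
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        raise EllipseFitError("tangent lines are parallel (no converging point)")
    return np.linalg.solve(A, b)
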