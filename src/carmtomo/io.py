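"""File formats: volumes, projection stacks, meshes, angle logs.

Volumes go through MetaImage / NIfTI (SimpleITK), projections through
multi-page TIFF or raw float32, both with a JSON sidecar holding the
per-view geometry; meshes through STL (trimesh).  The angle-log reader
implements the inclinometer conventions of a hand-rotated C-arm: ten-reading
averaging per position and conversion of relative increments to absolute
angles in [0, 360).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .containers import ProjectionSet, SurfaceMask, Volume
from .geometry import load_geometry, save_geometry

__all__ = [
    "write_volume",
    "read_volume",
    "read_mask",
    "write_projections",
    "read_projections",
    "write_mesh",
    "read_mesh",
    "average_readings",
    "angles_from_increments",
    "unwrap_inclinometer",
    "read_angle_log",
    "config_hash",
]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(vol: Volume, path) -> None:
    """Write a volume as MetaImage (.mha) or NIfTI (.nii/.nii.gz)."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.data.astype(np.float32).transpose(2, 1, 0))
    )
    img.SetSpacing((vol.voxel_size,) * 3)
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> Volume:
    img = sitk.ReadImage(str(path))
    sp = img.GetSpacing()
    if abs(sp[0] - sp[1]) > 1e-9 or abs(sp[0] - sp[2]) > 1e-9:
        raise ValueError(f"{path}: anisotropic voxels are not supported")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(data, float(sp[0]), np.array(img.GetOrigin()))


def read_mask(path) -> SurfaceMask:
    v = read_volume(path)
    return SurfaceMask(v.data > 0.5, v.voxel_size, v.origin)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def write_projections(proj: ProjectionSet, path, fmt: str = "tiff") -> None:
    """Projection stack + geometry sidecar.

    ``fmt='tiff'``: multi-page float32 TIFF; ``fmt='raw'``: flat float32
    with shape recorded in the sidecar.  The sidecar (``<path>.json``)
    carries the full per-view geometry, so a stack is self-describing.
    """
    path = Path(path)
    data = np.ascontiguousarray(proj.data.astype(np.float32))
    if fmt == "tiff":
        tifffile.imwrite(path, data)
    elif fmt == "raw":
        data.tofile(path)
    else:
        raise ValueError(f"unknown projection format {fmt!r}")
    side = path.with_suffix(path.suffix + ".json")
    save_geometry(proj.trajectory, side)
    with open(side) as fh:
        doc = json.load(fh)
    doc["stack"] = {
        "format": fmt,
        "shape": list(data.shape),
        "dtype": "float32",
        "meta": {k: v for k, v in proj.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    with open(side, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_projections(path) -> ProjectionSet:
    path = Path(path)
    side = path.with_suffix(path.suffix + ".json")
    if not side.exists():
        raise FileNotFoundError(f"missing geometry sidecar {side}")
    traj = load_geometry(side)
    with open(side) as fh:
        doc = json.load(fh)
    stack = doc.get("stack", {})
    if stack.get("format") == "raw":
        data = np.fromfile(path, dtype=np.float32).reshape(stack["shape"])
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    return ProjectionSet(data, traj, dict(stack.get("meta", {})))


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh(mesh, path) -> None:
    mesh.export(str(path))


def read_mesh(path):
    import trimesh

    mesh = trimesh.load_mesh(str(path))
    return mesh


# ---------------------------------------------------------------------------
# inclinometer angle logs
# ---------------------------------------------------------------------------

def average_readings(readings, n: int = 10) -> np.ndarray:
    """Mean of consecutive groups of ``n`` readings (vibration smoothing)."""
    r = np.asarray(readings, dtype=float)
    if len(r) % n:
        raise ValueError(f"reading count {len(r)} not a multiple of {n}")
    return r.reshape(-1, n).mean(axis=1)


def angles_from_increments(increments) -> np.ndarray:
    """Absolute angles in [0, 360) from relative increments."""
    inc = np.asarray(increments, dtype=float)
    return np.cumsum(inc) % 360.0


def unwrap_inclinometer(
    readings, hysteresis: float = 0.5, start: float = 0.0
) -> np.ndarray:
    """Absolute angles from wrapped inclinometer readings in [-90, 90].

    A pendulum inclinometer cannot distinguish an angle from its mirror;
    the rotation direction is estimated from smoothed finite differences
    (with ``hysteresis`` degrees of tolerance before a direction switch is
    accepted), and each reading is lifted to the candidate absolute angle
    closest to the extrapolated trajectory.
    """
    r = np.asarray(readings, dtype=float)
    out = np.empty_like(r)
    out[0] = start if abs(start) > 0 else r[0] % 360.0
    trend = 0.0
    for i in range(1, len(r)):
        cands = np.array(
            [r[i] % 360.0, (180.0 - r[i]) % 360.0]
        )
        # candidates shifted by full turns around the previous estimate
        all_c = np.concatenate([cands + k * 360.0 for k in (-1, 0, 1)])
        predicted = out[i - 1] + trend
        j = int(np.argmin(np.abs(all_c - predicted)))
        out[i] = all_c[j]
        step = out[i] - out[i - 1]
        if trend == 0.0 or abs(step) > hysteresis:
            trend = 0.7 * trend + 0.3 * step
    return out % 360.0


def read_angle_log(
    path, n_average: int = 10, mode: str = "increments"
) -> np.ndarray:
    """Angle list from an inclinometer-style CSV log (one reading per row).

    Consecutive groups of ``n_average`` readings are averaged first; then
    ``mode='increments'`` accumulates relative increments into absolute
    angles, while ``mode='wrapped'`` unwraps pendulum readings.
    """
    raw = np.loadtxt(path, delimiter=",", ndmin=1)
    if raw.ndim > 1:
        raw = raw[:, -1]
    avg = average_readings(raw, n_average) if n_average > 1 else raw
    if mode == "increments":
        return angles_from_increments(avg)
    if mode == "wrapped":
        return unwrap_inclinometer(avg)
    raise ValueError(f"unknown angle-log mode {mode!r}")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
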