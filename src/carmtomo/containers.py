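"""In-memory containers: voxel volumes, binary support masks, projection sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DetectorSpec, Trajectory

__all__ = ["Volume", "SurfaceMask", "ProjectionSet"]


@dataclass
class Volume:
    """A 3D image on a regular voxel grid.

    ``data`` is indexed ``[ix, iy, iz]``; the world position of voxel centre
    ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size``.  By default the grid
    is centred on the world origin.  ``voxel_size`` is isotropic, in mm.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.origin is None:
            n = np.array(self.data.shape, dtype=float)
            self.origin = -(n - 1) / 2.0 * self.voxel_size
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) < atol
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.voxel_size, self.origin.copy())

    def world_coords(self):
        """1-D world coordinate arrays (x, y, z) of the voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.data.shape[a]) * self.voxel_size
            for a in range(3)
        )


class SurfaceMask(Volume):
    """Binary support Ω of a sample on a voxel grid (non-zero = inside)."""

    def __post_init__(self):
        super().__post_init__()
        self.data = np.ascontiguousarray(self.data != 0)

    @property
    def n_inside(self) -> int:
        return int(self.data.sum())


@dataclass
class ProjectionSet:
    """Stack of 2-D projections with their per-view geometry.

    ``data`` has shape ``(n_views, n_v, n_h)`` (view, detector row, column);
    row index is the ``v`` pixel coordinate, column index ``h``.
    """

    data: np.ndarray
    trajectory: Trajectory
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("projection data must be (n_views, n_v, n_h)")
        det = self.trajectory.detector
        if self.data.shape[0] != len(self.trajectory):
            raise ValueError("view count mismatch between data and trajectory")
        if self.data.shape[1:] != (det.n_v, det.n_h):
            raise ValueError("projection shape does not match detector spec")

    @property
    def detector(self) -> DetectorSpec:
        return self.trajectory.detector

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    def copy_with(self, data: np.ndarray) -> "ProjectionSet":
        return ProjectionSet(data, self.trajectory, dict(self.meta))
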