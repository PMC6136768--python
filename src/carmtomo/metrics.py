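"""Quantitative image-quality metrics for limited-data reconstructions.

Two complementary measures against a reference CT volume:

* **SAI** (Streak Artifact Indicator) — total variation of the difference
  between the reconstruction and the reference, computed with in-slice 2-D
  gradients.  Streaks add spurious edges, which TV picks up.
* **LiVA** (Limited View Artifact) — RMSE between reconstruction and
  reference inside a region of interest bounded by the sample's external
  contour, capturing the shape distortion of limited-angle scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import SurfaceMask, Volume

__all__ = ["MetricReport", "sai", "liva", "roi_from_reference", "evaluate"]


@dataclass
class MetricReport:
    sai: float
    liva: float
    roi_voxels: int
    normalization: str  # "raw" or "per-voxel"

    def as_dict(self) -> dict:
        return {
            "sai": self.sai,
            "liva": self.liva,
            "roi_voxels": self.roi_voxels,
            "normalization": self.normalization,
        }


def _check_same_grid(a: Volume, b: Volume):
    if not a.same_grid(b):
        raise ValueError(
            "volumes are not on the same grid; resample explicitly first"
        )


def _tv2d(diff: np.ndarray) -> float:
    """Sum of in-slice (x, y) gradient magnitudes, forward differences."""
    gx = np.diff(diff, axis=0, append=diff[-1:, :, :])
    gy = np.diff(diff, axis=1, append=diff[:, -1:, :])
    return float(np.sqrt(gx**2 + gy**2).sum())


def sai(recon: Volume, reference: Volume, normalize: bool = False) -> float:
    """Streak Artifact Indicator: TV of (recon - reference).

    With ``normalize`` the value is divided by the voxel count (the raw
    value scales with volume size; the normalization mode is recorded in
    :class:`MetricReport`).
    """
    _check_same_grid(recon, reference)
    d = recon.data.astype(np.float64) - reference.data.astype(np.float64)
    v = _tv2d(d)
    if normalize:
        v /= d.size
    return v


def liva(recon: Volume, reference: Volume, roi: SurfaceMask) -> float:
    """Limited View Artifact: RMSE inside the sample-contour ROI."""
    _check_same_grid(recon, reference)
    _check_same_grid(recon, roi)
    m = roi.data
    if not m.any():
        raise ValueError("empty ROI")
    d = recon.data.astype(np.float64) - reference.data.astype(np.float64)
    return float(np.sqrt(np.mean(d[m] ** 2)))


def roi_from_reference(
    reference: Volume, threshold: float | None = None, relative: float = 0.2
) -> SurfaceMask:
    """ROI bounded by the external contour of the sample.

    Threshold (absolute, or ``relative`` fraction of the max), largest
    connected component, morphological closing and hole filling.
    """
    data = reference.data
    thr = threshold if threshold is not None else relative * float(data.max())
    binary = data > thr
    if not binary.any():
        raise ValueError("no voxels above threshold; is the volume empty?")
    lab, n = ndimage.label(binary)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = lab == biggest
    # pad before closing so objects touching the volume face are not eroded
    padded = np.pad(mask, 2, mode="edge")
    padded = ndimage.binary_closing(padded, iterations=2)
    padded = ndimage.binary_fill_holes(padded)
    mask = padded[2:-2, 2:-2, 2:-2]
    if not mask.any():
        raise ValueError("ROI extraction produced an empty mask")
    return SurfaceMask(mask, reference.voxel_size, reference.origin.copy())


def evaluate(
    recon: Volume,
    reference: Volume,
    roi: SurfaceMask | None = None,
    normalize_sai: bool = False,
) -> MetricReport:
    """SAI + LiVA in one report; the ROI defaults to the reference contour."""
    if roi is None:
        roi = roi_from_reference(reference)
    return MetricReport(
        sai=sai(recon, reference, normalize=normalize_sai),
        liva=liva(recon, reference, roi),
        roi_voxels=roi.n_inside,
        normalization="per-voxel" if normalize_sai else "raw",
    )
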