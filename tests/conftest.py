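import numpy as np
import pytest

from carmtomo import (
    CalibPhantomSpec,
    DetectorSpec,
    make_circular_trajectory,
    simulate_calib_projection,
)
from carmtomo.geometry import make_view_geometry, project_points

# the flat-panel acquisition used throughout: 444x540 pixels of 0.8 mm,
# SDD 1250 mm / SOD 625 mm (magnification 2)
SDD, SOD = 1250.0, 625.0


@pytest.fixture(scope="session")
def detector():
    return DetectorSpec(444, 540, 0.8)


@pytest.fixture(scope="session")
def phantom():
    return CalibPhantomSpec()


@pytest.fixture(scope="session")
def small_detector():
    return DetectorSpec(96, 80, 2.0)


def view_with(detector, **kw):
    """A single view at the default SDD/SOD with given misalignments."""
    return make_view_geometry(kw.pop("angle", 0.0), kw.pop("sdd", SDD),
                              kw.pop("sod", SOD), detector, **kw)


def bead_pixels(phantom, geom, detector):
    """Exact projections of the phantom beads, (upper, lower) rings."""
    up, lo = phantom.bead_centers()
    return (
        project_points(geom, detector, up),
        project_points(geom, detector, lo),
    )


@pytest.fixture(scope="session")
def ideal_view(detector):
    return view_with(detector)


@pytest.fixture(scope="session")
def ideal_calib_projection(phantom, ideal_view, detector):
    return simulate_calib_projection(phantom, ideal_view, detector)


@pytest.fixture(scope="session")
def limb_sample():
    from carmtomo import make_digital_sample

    return make_digital_sample("ellipsoid-limb", size=48, voxel_size=1.5,
                               seed=0)


@pytest.fixture(scope="session")
def limited_scan(limb_sample, small_detector):
    """25-view / 120-degree scan of the limb sample (the limited-data
    benchmark geometry)."""
    from carmtomo import simulate_scan

    traj = make_circular_trajectory(25, 120.0, 1000.0, 500.0, small_detector)
    return simulate_scan(limb_sample.volume, traj)
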