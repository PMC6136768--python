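import warnings

import numpy as np
import pytest

from carmtomo import (
    CalibPhantomSpec,
    GeometryPerturbation,
    Trajectory,
    make_circular_trajectory,
    perturb_trajectory,
    simulate_calib_projection,
    simulate_calib_scan,
)
from carmtomo.calibration import (
    CalibrationError,
    MarkerSet,
    calibrate_scan,
    calibrate_view,
    classify_rings,
    estimate_offsets_and_skew,
    estimate_pitch,
    estimate_roll,
    estimate_source_detector,
    make_ellipse_pair,
    roll_cost,
    segment_markers,
)

from conftest import SDD, SOD, bead_pixels, view_with


def pair_for(phantom, detector, **kw):
    pu, pl = bead_pixels(phantom, view_with(detector, **kw), detector)
    return make_ellipse_pair(pu, pl, detector.pixel_size)


def markers_for(phantom, detector, **kw):
    pu, pl = bead_pixels(phantom, view_with(detector, **kw), detector)
    return MarkerSet(
        np.vstack([pu, pl]),
        labels=np.r_[np.zeros(len(pu), int), np.ones(len(pl), int)],
    )


class TestSegmentation:
    def test_blank_image_gives_empty_marker_set(self):
        assert len(segment_markers(np.zeros((64, 64)))) == 0

    def test_synthetic_blobs_recovered_to_subpixel(self, phantom, detector):
        """16 rendered beads at known positions -> 16 centroids < 0.2 px."""
        cp = simulate_calib_projection(
            phantom, view_with(detector), detector
        )
        mk = segment_markers(cp.image)
        truth = np.vstack([cp.true_upper, cp.true_lower])
        assert len(mk) == 16
        for c in mk.centroids:
            assert np.min(np.linalg.norm(truth - c, axis=1)) < 0.2

    def test_phantom_projection_has_8_centroids_per_ring(
        self, phantom, ideal_calib_projection
    ):
        mk = classify_rings(segment_markers(ideal_calib_projection.image))
        assert len(mk.ring("upper")) == 8
        assert len(mk.ring("lower")) == 8

    def test_overrides_add_and_remove(self, ideal_calib_projection):
        mk0 = segment_markers(ideal_calib_projection.image)
        victim = tuple(mk0.centroids[0])
        mk = segment_markers(
            ideal_calib_projection.image,
            overrides={"remove": [victim], "add": [(10.0, 12.0)]},
        )
        assert len(mk) == len(mk0)
        assert any(np.allclose(c, (10.0, 12.0)) for c in mk.centroids)


class TestClassifyRings:
    def test_split_matches_generator_labels(self, phantom, detector):
        cp = simulate_calib_projection(
            phantom, view_with(detector, pitch=5.0), detector
        )
        mk = classify_rings(segment_markers(cp.image))
        up = mk.ring("upper")
        for c in up:
            assert np.min(
                np.linalg.norm(cp.true_upper - c, axis=1)
            ) < 0.5

    def test_permutation_invariance(self, phantom, detector):
        pu, pl = bead_pixels(phantom, view_with(detector), detector)
        pts = np.vstack([pu, pl])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pts))
        a = classify_rings(MarkerSet(pts))
        b = classify_rings(MarkerSet(pts[perm]))
        assert np.allclose(
            np.sort(a.ring("upper"), axis=0),
            np.sort(b.ring("upper"), axis=0),
        )

    def test_collinear_markers_rejected(self):
        pts = np.column_stack([np.arange(16.0), np.arange(16.0) * 0.5])
        with pytest.raises(CalibrationError):
            classify_rings(MarkerSet(pts))

    def test_too_few_markers_rejected(self):
        with pytest.raises(CalibrationError):
            classify_rings(MarkerSet(np.random.default_rng(0).random((8, 2))))


class TestOffsetsAndSkew:
    def test_centered_symmetric_pair(self, phantom, detector):
        pair = pair_for(phantom, detector)
        oh, ov, eta = estimate_offsets_and_skew(pair, detector)
        assert oh == pytest.approx(0.0, abs=1e-9)
        assert ov == pytest.approx(0.0, abs=1e-9)
        assert eta == pytest.approx(0.0, abs=1e-9)

    def test_skew_recovered_within_tenth_degree(self, phantom, detector):
        pair = pair_for(phantom, detector, skew=5.0)
        _, _, eta = estimate_offsets_and_skew(pair, detector)
        assert eta == pytest.approx(5.0, abs=0.1)

    def test_offsets_recovered_within_third_pixel(self, phantom, detector):
        pair = pair_for(phantom, detector, offset_h=12.0, offset_v=-7.0)
        oh, ov, _ = estimate_offsets_and_skew(pair, detector)
        assert oh == pytest.approx(12.0, abs=0.3)
        assert ov == pytest.approx(-7.0, abs=0.3)


class TestPitch:
    def test_equal_extents_give_zero_pitch(self, phantom, detector):
        # pure roll keeps the two ellipses congruent ("same shape")
        pair = pair_for(phantom, detector, roll=25.0)
        assert estimate_pitch(pair, phantom) == 0.0

    def test_pitch_60_degrees_within_1(self, phantom, detector):
        pair = pair_for(phantom, detector, pitch=60.0)
        assert estimate_pitch(pair, phantom, phi=0.0) == pytest.approx(
            60.0, abs=1.0
        )

    @pytest.mark.parametrize("theta", [10.0, -10.0])
    def test_pitch_10_degrees_within_half(self, phantom, detector, theta):
        pair = pair_for(phantom, detector, pitch=theta)
        assert estimate_pitch(pair, phantom, phi=0.0) == pytest.approx(
            theta, abs=0.5
        )


class TestRoll:
    def test_parallel_axes_give_zero_roll(self, phantom, detector):
        pair = pair_for(phantom, detector)
        theta = estimate_pitch(pair, phantom)
        phi, cost = estimate_roll(pair, pair.z_s, phantom, detector,
                                  theta=theta)
        assert abs(phi) < 0.2
        assert cost < 1e-6

    def test_roll_60_degrees_within_1(self, phantom, detector):
        pair = pair_for(phantom, detector, roll=60.0)
        theta = estimate_pitch(pair, phantom)
        phi, _ = estimate_roll(pair, pair.z_s, phantom, detector,
                               theta=theta)
        assert phi == pytest.approx(60.0, abs=1.0)

    def test_simplex_agrees_with_grid_search(self, phantom, detector):
        """The Nelder-Mead optimum matches a 0.1-degree brute-force grid
        scan of the same cost within 0.2 degrees."""
        pair = pair_for(phantom, detector, roll=20.0)
        theta = estimate_pitch(pair, phantom)
        phi, _ = estimate_roll(pair, pair.z_s, phantom, detector,
                               theta=theta)
        sdd = pair.z_s * np.cos(np.radians(theta))
        nuis0 = np.array([pair.midpoint[0], SOD, sdd])
        grid = np.arange(phi - 4.0, phi + 4.0, 0.1)
        costs = [
            roll_cost(g, pair, phantom, detector, theta,
                      float(pair.midpoint[1]), nuis0)
            for g in grid
        ]
        assert abs(grid[int(np.argmin(costs))] - phi) <= 0.2


class TestSourceDetector:
    def test_sdd_recovered_within_1_percent(self, phantom, detector):
        pair = pair_for(phantom, detector)
        theta = estimate_pitch(pair, phantom)
        geom = estimate_source_detector(
            pair, phantom, detector, (0.0, 0.0), 0.0, theta, 0.0
        )
        assert geom.sdd == pytest.approx(SDD, rel=0.01)

    def test_magnification_reproduces_major_axis(self, phantom, detector):
        pair = pair_for(phantom, detector)
        geom = estimate_source_detector(
            pair, phantom, detector, (0.0, 0.0), 0.0, 0.0, 0.0
        )
        sod = np.linalg.norm(geom.source_pos)
        a_px, _, _ = pair.upper.axes()
        predicted = (
            2 * phantom.radius * (geom.sdd / sod) / detector.pixel_size
        )
        assert 2 * a_px == pytest.approx(predicted, rel=0.01)

    def test_sod_shift_moves_recovered_source(self, phantom, detector):
        g1 = estimate_source_detector(
            pair_for(phantom, detector, sod=SOD), phantom, detector,
            (0.0, 0.0), 0.0, 0.0, 0.0,
        )
        g2 = estimate_source_detector(
            pair_for(phantom, detector, sod=SOD + 25.0), phantom, detector,
            (0.0, 0.0), 0.0, 0.0, 0.0,
        )
        d1 = np.linalg.norm(g1.source_pos)
        d2 = np.linalg.norm(g2.source_pos)
        assert d2 - d1 == pytest.approx(25.0, abs=2.0)


class TestCalibrateView:
    def test_ideal_view_recovers_identity(self, phantom, detector):
        geom, q = calibrate_view(
            markers_for(phantom, detector), phantom, detector
        )
        assert abs(geom.skew) < 0.05
        assert abs(geom.pitch) < 0.2
        assert abs(geom.roll) < 0.2
        assert abs(geom.offset_h) < 0.1 and abs(geom.offset_v) < 0.1

    def test_combined_misalignments_recovered(self, phantom, detector):
        true = dict(skew=-6.0, pitch=9.0, roll=-4.0, offset_h=14.0,
                    offset_v=-11.0)
        geom, _ = calibrate_view(
            markers_for(phantom, detector, **true), phantom, detector
        )
        assert geom.skew == pytest.approx(true["skew"], abs=0.05)
        assert geom.pitch == pytest.approx(true["pitch"], abs=0.2)
        assert geom.roll == pytest.approx(true["roll"], abs=0.2)
        assert geom.offset_h == pytest.approx(true["offset_h"], abs=0.1)

    def test_calibration_is_deterministic(self, phantom, detector,
                                          ideal_calib_projection):
        img = ideal_calib_projection.image
        g1, _q1 = calibrate_view(img, phantom, detector)
        g2, _q2 = calibrate_view(img, phantom, detector)
        assert g1.skew == g2.skew
        assert g1.pitch == g2.pitch
        assert np.array_equal(g1.detector_pos, g2.detector_pos)


class TestCalibrateScan:
    @pytest.fixture(scope="class")
    def perturbed_scan(self, phantom, detector):
        rng = np.random.default_rng(2024)
        views, truths = [], []
        for a in np.linspace(0.0, 120.0, 25):
            eta, th, ph = rng.uniform(-15, 15, 3)
            oh, ov = rng.uniform(-20, 20, 2)
            views.append(
                view_with(detector, angle=a, skew=eta, pitch=th, roll=ph,
                          offset_h=oh, offset_v=ov)
            )
            truths.append((eta, th, ph, oh, ov))
        traj = Trajectory(views, detector, 120.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps, _ = simulate_calib_scan(phantom, traj)
        return ps, truths

    def test_full_sweep_recovery(self, perturbed_scan, phantom):
        """25-view sweep with skew/pitch/roll in [-15, 15] degrees and
        offsets in [-20, 20] px: recovered within (0.2, 1, 1) degrees and
        0.5 px — the module's primary accuracy contract."""
        ps, truths = perturbed_scan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cal, report = calibrate_scan(ps, phantom)
        assert all(r["ok"] for r in report)
        worst = np.zeros(5)
        for g, t in zip(cal.views, truths):
            err = np.abs([g.skew - t[0], g.pitch - t[1], g.roll - t[2],
                          g.offset_h - t[3], g.offset_v - t[4]])
            worst = np.maximum(worst, err)
        assert worst[0] <= 0.2  # skew, degrees
        assert worst[1] <= 1.0  # pitch
        assert worst[2] <= 1.0  # roll
        assert worst[3] <= 0.5 and worst[4] <= 0.5  # offsets, px

    def test_blank_frame_is_flagged_not_fatal(self, phantom, detector):
        traj = make_circular_trajectory(5, 40.0, SDD, SOD, detector)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps, _ = simulate_calib_scan(phantom, traj)
            ps.data[2] = 0.0
            cal, report = calibrate_scan(ps, phantom)
        assert not report[2]["ok"]
        assert sum(r["ok"] for r in report) == 4

    def test_all_blank_scan_fails(self, phantom, detector):
        traj = make_circular_trajectory(5, 40.0, SDD, SOD, detector)
        data = np.zeros((5, detector.n_v, detector.n_h), np.float32)
        from carmtomo.containers import ProjectionSet

        with pytest.raises(CalibrationError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                calibrate_scan(ProjectionSet(data, traj), phantom)
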