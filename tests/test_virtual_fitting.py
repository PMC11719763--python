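import numpy as np
import pandas as pd
import pytest

from lifuplan.array_model import TransducerPose
from lifuplan.exceptions import NoValidPlacementError
from lifuplan.steering_limits import SteeringMap
from lifuplan.virtual_fitting import (FitCandidate, angles_to_direction,
                                      candidate_positions, evaluate_candidates,
                                      optimize_placement,
                                      place_virtual_transducer, plot_fit_report,
                                      segment_skin)

from conftest import PHANTOM_TARGET, assert_rotation


class TestAngles:
    def test_unit_directions(self):
        d = angles_to_direction([0.0, 10.0, -5.0], [0.0, 20.0, 40.0])
        np.testing.assert_allclose(np.linalg.norm(d, axis=-1), 1.0)

    def test_reference_directions(self):
        np.testing.assert_allclose(angles_to_direction(0.0, 0.0), [0, 1, 0],
                                   atol=1e-12)
        # positive azimuth leans toward the subject's left (-x)
        assert angles_to_direction(30.0, 0.0)[0] < 0
        # positive elevation leans superior (+z)
        assert angles_to_direction(0.0, 30.0)[2] > 0


class TestCandidatePositions:
    def test_default_count(self):
        cands = candidate_positions()
        assert len(cands) == 121

    def test_ranges(self):
        cands = np.asarray(candidate_positions())
        assert cands[:, 0].min() == 10.0 and cands[:, 0].max() == 40.0
        assert cands[:, 1].min() == -5.0 and cands[:, 1].max() == 25.0


class TestSkinSegmentation:
    def test_radii_near_surface(self, phantom_1mm):
        """The segmented skin radius matches the outer ellipsoid along each
        stencil direction to within a couple of voxels."""
        spec, vol, _ = phantom_1mm
        surface = segment_skin(vol, 500.0)
        radii = np.asarray(spec.head_radii)
        for el, az in [(10.0, 0.0), (25.0, 10.0), (40.0, -5.0)]:
            d = angles_to_direction(az, el)
            expected = 1.0 / np.linalg.norm(d / radii)
            assert surface.radius_at(el, az) == pytest.approx(expected,
                                                              abs=2.5)

    def test_empty_volume_rejected(self):
        from lifuplan.head_volume import HeadVolume

        vol = HeadVolume(np.zeros((8, 8, 8)), np.diag([10.0, 10, 10, 1]))
        with pytest.raises(ValueError):
            segment_skin(vol, 500.0)


class TestPlacement:
    def test_pose_geometry(self, phantom_1mm):
        spec, vol, _ = phantom_1mm
        surface = segment_skin(vol, 500.0)
        pose = place_virtual_transducer(surface, (25.0, 0.0))
        assert_rotation(pose.axes)
        # origin sits roughly pad_thickness above the skin surface
        f = np.linalg.norm(pose.origin / np.asarray(spec.head_radii))
        assert 1.0 < f < 1.25
        # axial axis points into the head (toward the origin region)
        assert np.dot(pose.axes[:, 2], -pose.origin) > 0

    def test_wedge_tilts_beam_down(self, phantom_1mm):
        spec, vol, _ = phantom_1mm
        surface = segment_skin(vol, 500.0)
        flat = place_virtual_transducer(surface, (25.0, 0.0), wedge_deg=0.0)
        wedged = place_virtual_transducer(surface, (25.0, 0.0), wedge_deg=10.0)
        # the wedged axial axis points more inferior (smaller z component)
        assert wedged.axes[2, 2] < flat.axes[2, 2]
        angle = np.degrees(np.arccos(np.clip(
            np.dot(flat.axes[:, 2], wedged.axes[:, 2]), -1, 1)))
        assert angle == pytest.approx(10.0, abs=1e-6)


def _candidate(elev, azim, valid=True, blocked=0, dist=50.0):
    return FitCandidate(elevation_deg=elev, azimuth_deg=azim,
                        pose=TransducerPose.identity(),
                        steering_offset_mm=np.zeros(3),
                        target_in_frame_mm=np.array([0.0, 0.0, 50.0]),
                        n_blocked=blocked, distance_to_target_mm=dist,
                        steering_valid=valid)


class TestOptimizer:
    def test_invalid_all_raises(self):
        with pytest.raises(NoValidPlacementError):
            optimize_placement([_candidate(10, 0, valid=False)])

    def test_empty_raises(self):
        with pytest.raises(NoValidPlacementError):
            optimize_placement([])

    def test_lowest_decile_then_distance(self):
        cands = ([_candidate(10, i, blocked=0, dist=60.0 - i)
                  for i in range(3)]
                 + [_candidate(20, i, blocked=50, dist=10.0)
                    for i in range(7)])
        best, report = optimize_placement(cands)
        # the blocked=50 candidates are closer but outside the lowest decile
        assert best.n_blocked == 0
        assert best.distance_to_target_mm == 58.0
        assert report.selected.sum() == 1

    def test_distance_tie_breaks_on_elevation_then_azimuth(self):
        cands = [_candidate(20, 5, dist=40.0), _candidate(10, 9, dist=40.0),
                 _candidate(10, 3, dist=40.0)]
        best, _ = optimize_placement(cands)
        assert (best.elevation_deg, best.azimuth_deg) == (10, 3)

    def test_steering_invalid_excluded(self):
        cands = [_candidate(10, 0, valid=False, dist=1.0),
                 _candidate(20, 0, valid=True, dist=99.0)]
        best, _ = optimize_placement(cands)
        assert best.distance_to_target_mm == 99.0

    def test_report_plot(self):
        cands = [_candidate(10, 0), _candidate(13, 3, valid=False)]
        _, report = optimize_placement(cands)
        ax = plot_fit_report(report)
        assert ax is not None


class TestEndToEnd:
    def test_pipeline_properties(self, phantom_1mm, geom):
        """The winner is steering-valid, in the lowest blocked decile, and
        the closest such candidate to the target."""
        spec, vol, truth = phantom_1mm
        surface = segment_skin(vol, 500.0)
        smap = SteeringMap.from_box()
        cands = evaluate_candidates(vol, surface, PHANTOM_TARGET, geom, smap)
        assert len(cands) == 121
        best, report = optimize_placement(cands)
        assert best.steering_valid
        valid = [c for c in cands if c.steering_valid]
        counts = np.array([c.n_blocked for c in valid])
        cutoff = np.percentile(counts, 10.0, method="inverted_cdf")
        pool = [c for c in valid if c.n_blocked <= cutoff]
        assert best.n_blocked <= cutoff
        assert best.distance_to_target_mm == min(c.distance_to_target_mm
                                                 for c in pool)
        assert isinstance(report, pd.DataFrame) and len(report) == 121
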