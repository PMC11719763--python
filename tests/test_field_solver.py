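import numpy as np
import pytest

from lifuplan.exceptions import InvalidTargetError, UnreachableTargetError
from lifuplan.field_solver import (LABELS, GridSpec, Medium, PressureField,
                                   Solution, compute_delays,
                                   propagate_heterogeneous, scale_to_pnp,
                                   simulate_field, uniform_solution)

NOMINAL = (0.0, 0.0, 50.0)


class TestDelays:
    def test_nonnegative_with_zero_min(self, geom):
        d = compute_delays(geom, NOMINAL)
        assert d.min() == pytest.approx(0.0)
        assert (d >= 0).all()

    def test_time_of_flight_identity(self, geom):
        """delay + distance/c is the same constant for every element."""
        from lifuplan.array_model import element_target_distances

        d = compute_delays(geom, (4.0, -7.0, 55.0))
        dist = element_target_distances(geom, (4.0, -7.0, 55.0))
        arrival = d + dist / 1.54
        np.testing.assert_allclose(arrival, arrival[0], atol=1e-9)

    def test_lateral_mirror_symmetry(self, geom):
        perm = geom.mirror_index_map()
        d = compute_delays(geom, (6.0, 2.0, 50.0))
        dm = compute_delays(geom, (-6.0, 2.0, 50.0))
        np.testing.assert_allclose(dm, d[perm], atol=1e-9)

    def test_target_behind_array_rejected(self, geom):
        with pytest.raises(InvalidTargetError):
            compute_delays(geom, (0.0, 0.0, -10.0))


class TestSolution:
    def test_uniform(self, geom):
        sol = uniform_solution(geom, NOMINAL)
        assert sol.apodization.shape == (geom.n_active,)
        assert (sol.apodization == 1.0).all()

    def test_rejects_negative_delay(self):
        with pytest.raises(ValueError):
            Solution(delays_us=np.array([-1.0]), apodization=np.array([1.0]))

    def test_rejects_bad_apodization(self):
        with pytest.raises(ValueError):
            Solution(delays_us=np.zeros(2), apodization=np.array([0.5, 1.5]))

    def test_scaled_sets_voltage(self, geom):
        sol = uniform_solution(geom, NOMINAL).scaled(100.0)
        assert sol.source_pressure_kpa == pytest.approx(100.0)
        assert sol.drive_voltage_v == pytest.approx(4.0)  # 25 kPa per volt


class TestGridAndField:
    def test_from_bounds(self):
        g = GridSpec.from_bounds((-5, -5, 40), (5, 5, 60), 2.5)
        assert g.shape == (5, 5, 9)
        assert g.contains((0, 0, 50)) and not g.contains((0, 0, 80))

    def test_points_order(self):
        g = GridSpec((0, 0, 0), 1.0, (2, 2, 2))
        pts = g.points()
        np.testing.assert_allclose(pts[0], [0, 0, 0])
        np.testing.assert_allclose(pts[1], [0, 0, 1])  # z fastest (C order)

    def test_field_npz_round_trip(self, nominal_field_2mm, tmp_path):
        path = tmp_path / "f.npz"
        nominal_field_2mm.save_npz(path)
        f2 = PressureField.load_npz(path)
        np.testing.assert_allclose(f2.amplitude, nominal_field_2mm.amplitude)
        np.testing.assert_allclose(f2.phase, nominal_field_2mm.phase)

    def test_amplitude_at_matches_voxel(self, nominal_field_2mm):
        peak, loc = nominal_field_2mm.peak()
        assert nominal_field_2mm.amplitude_at(loc) == pytest.approx(peak)

    def test_to_nifti_affine(self, nominal_field_2mm):
        img = nominal_field_2mm.to_nifti()
        np.testing.assert_allclose(img.affine[:3, 3],
                                   nominal_field_2mm.grid_origin)


class TestSimulatedFocus:
    def test_peak_near_target(self, nominal_field_1mm):
        """The focus forms near the requested target, shifted slightly
        toward the array (finite-aperture axial shift)."""
        peak, loc = nominal_field_1mm.peak()
        assert abs(loc[0]) <= 1.0 and abs(loc[1]) <= 1.0
        assert 44.0 <= loc[2] <= 50.5
        assert loc[2] <= 50.0  # shift is toward the array, not beyond

    def test_scale_to_pnp_hits_target(self, nominal_field_1mm):
        assert nominal_field_1mm.amplitude_at(NOMINAL) == pytest.approx(820.0)

    def test_focal_gain(self, geom, medium):
        """Focal amplitude is many times the source pressure (gain >> 1)."""
        from lifuplan.field_solver import pressure_at_points

        sol = uniform_solution(geom, NOMINAL)
        p = np.abs(pressure_at_points(geom, sol, medium, NOMINAL))[0]
        assert p > 5.0  # gain over unit source pressure

    def test_steered_focus_lands_at_offset_target(self, geom, medium):
        target = (6.0, -4.0, 48.0)
        sol = uniform_solution(geom, target)
        grid = GridSpec.from_bounds((-2 + 6, -2 - 4, 40), (2 + 6, 2 - 4, 56),
                                    1.0)
        field = simulate_field(geom, sol, medium, grid)
        _, loc = field.peak()
        assert abs(loc[0] - 6.0) <= 1.0 and abs(loc[1] + 4.0) <= 1.0

    def test_aliasing_warning(self, geom, medium):
        grid = GridSpec.from_bounds((-2, -2, 48), (2, 2, 52), 2.5)
        with pytest.warns(UserWarning, match="aliased"):
            simulate_field(geom, uniform_solution(geom, NOMINAL), medium, grid)

    def test_unreachable_target(self, nominal_field_1mm, geom):
        zero = PressureField(nominal_field_1mm.grid_origin, 1.0,
                             np.zeros_like(nominal_field_1mm.amplitude))
        with pytest.raises(UnreachableTargetError):
            scale_to_pnp(zero, uniform_solution(geom, NOMINAL), NOMINAL, 820.0)


def _uniform_map(shape=(40, 40, 40), origin=(-39.0, -39.0, -4.0), spacing=2.0,
                 label="soft_tissue"):
    labels = np.full(shape, LABELS[label], np.int16)
    return Medium.from_labels(labels, origin, spacing)


class TestHeterogeneous:
    def test_requires_map(self, geom, medium):
        grid = GridSpec.from_bounds((-2, -2, 48), (2, 2, 52), 1.0)
        with pytest.raises(ValueError):
            propagate_heterogeneous(geom, uniform_solution(geom, NOMINAL),
                                    medium, grid)

    def test_air_gap_blocks_everything(self, geom):
        shape = (40, 40, 40)
        labels = np.full(shape, LABELS["soft_tissue"], np.int16)
        labels[:, :, 10:12] = LABELS["air"]  # air wall at z in [16, 20)
        med = Medium.from_labels(labels, (-39.0, -39.0, -4.0), 2.0)
        grid = GridSpec.from_bounds((-2, -2, 48), (2, 2, 52), 1.0)
        field = propagate_heterogeneous(geom, uniform_solution(geom, NOMINAL),
                                        med, grid)
        assert field.amplitude.max() == 0.0

    def test_skull_lowers_pressure(self, geom):
        """Qualitative direction: adding a skull layer drops the focal
        pressure relative to soft tissue alone."""
        shape = (40, 40, 40)
        origin = (-39.0, -39.0, -4.0)
        soft = np.full(shape, LABELS["soft_tissue"], np.int16)
        skull = soft.copy()
        zax = origin[2] + 2.0 * np.arange(shape[2])
        skull[:, :, (zax >= 10) & (zax < 16)] = LABELS["skull"]
        grid = GridSpec.from_bounds((-2, -2, 46), (2, 2, 54), 1.0)
        sol = uniform_solution(geom, NOMINAL)
        f_soft = propagate_heterogeneous(geom, sol,
                                         Medium.from_labels(soft, origin, 2.0),
                                         grid)
        f_skull = propagate_heterogeneous(geom, sol,
                                          Medium.from_labels(skull, origin, 2.0),
                                          grid)
        assert f_skull.amplitude.max() < f_soft.amplitude.max()
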