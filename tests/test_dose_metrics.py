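import math

import numpy as np
import pytest

from lifuplan.array_model import build_array
from lifuplan.dose_metrics import (DoseReport, acoustic_power,
                                   beam_widths, focal_distortion,
                                   grating_lobe_ratio, ispta_map,
                                   mechanical_index, pnp_to_isppa,
                                   sequence_power, thermal_index_cranium)
from lifuplan.field_solver import Medium, PressureField, Solution
from lifuplan.sequence import (build_timeline, phase_1_1_plan, phase_1_2_plan,
                               time_average_duty)


class TestClosedForms:
    def test_isppa_identity(self):
        # I = p^2 / (2 rho c), rho = 1050, c = 1540
        assert pnp_to_isppa(510.0) == pytest.approx(8.04, abs=0.005)
        assert pnp_to_isppa(650.0) == pytest.approx(13.1, abs=0.05)
        assert pnp_to_isppa(820.0) == pytest.approx(20.8, abs=0.05)

    def test_mechanical_index(self):
        assert mechanical_index(510.0, 400.0) == pytest.approx(0.806, abs=5e-4)
        assert mechanical_index(650.0, 400.0) == pytest.approx(1.03, abs=5e-3)
        assert mechanical_index(820.0, 400.0) == pytest.approx(1.3, abs=5e-3)
        with pytest.raises(ValueError):
            mechanical_index(510.0, 0.0)

    def test_tic_inversion(self):
        # TIC = W / (5.31 cm * 40 mW/cm): 3.0 corresponds to 637.2 mW
        assert thermal_index_cranium(637.2) == pytest.approx(3.0)
        assert thermal_index_cranium(0.0) == 0.0
        with pytest.raises(ValueError):
            thermal_index_cranium(-1.0)

    def test_single_element_power(self):
        """One 4.1 mm element at 100 kPa and full duty emits 51.98 mW."""
        g = build_array(n_rows=1, n_cols=1, curvature_radius=math.inf,
                        trim_corners=False)
        sol = Solution(delays_us=np.zeros(1), apodization=np.ones(1),
                       source_pressure_kpa=100.0)
        w = acoustic_power(sol, g, timeline_duty=1.0)
        assert w == pytest.approx(51.98, abs=0.01)

    def test_power_scales_with_duty_and_apodization(self, geom):
        sol = Solution(delays_us=np.zeros(geom.n_active),
                       apodization=np.ones(geom.n_active),
                       source_pressure_kpa=100.0)
        half = Solution(delays_us=np.zeros(geom.n_active),
                        apodization=np.full(geom.n_active, 0.5),
                        source_pressure_kpa=100.0)
        assert acoustic_power(sol, geom, 0.5) == pytest.approx(
            0.5 * acoustic_power(sol, geom, 1.0))
        assert acoustic_power(half, geom, 1.0) == pytest.approx(
            0.25 * acoustic_power(sol, geom, 1.0))

    def test_sequence_power_matches_sum(self, geom):
        plan = phase_1_2_plan()
        tl = build_timeline(plan, "interleaved")
        w = sequence_power([100.0] * 5, geom, tl)
        sol = Solution(delays_us=np.zeros(geom.n_active),
                       apodization=np.ones(geom.n_active),
                       source_pressure_kpa=100.0)
        expected = acoustic_power(sol, geom, time_average_duty(plan, tl))
        assert w == pytest.approx(expected)


def _gaussian_field(sigmas=(2.0, 3.0, 8.0), spacing=1.0, peak=800.0):
    grid = np.meshgrid(*[spacing * (np.arange(41) - 20)] * 3, indexing="ij")
    amp = peak * np.exp(-0.5 * sum((g / s) ** 2
                                   for g, s in zip(grid, sigmas)))
    return PressureField((-20.0, -20.0, 30.0), spacing, amp)


class TestBeamWidths:
    def test_gaussian_widths(self):
        """-6 dB (half-pressure) full width of a Gaussian is
        2 sigma sqrt(2 ln 2)."""
        f = _gaussian_field()
        for axis, sigma in zip(("lateral", "elevation", "axial"),
                               (2.0, 3.0, 8.0)):
            expected = 2.0 * sigma * math.sqrt(2.0 * math.log(2.0))
            assert beam_widths(f, -6.0, axis) == pytest.approx(expected,
                                                               rel=0.02)

    def test_level_scaling(self):
        f = _gaussian_field()
        w3 = beam_widths(f, -3.0, "lateral")
        w6 = beam_widths(f, -6.0, "lateral")
        assert w3 < w6
        # Gaussian: width ratio = sqrt(3/6), up to linear-interp error
        assert w3 / w6 == pytest.approx(math.sqrt(0.5), rel=0.05)

    def test_truncation_warns(self):
        f = _gaussian_field(sigmas=(40.0, 3.0, 8.0))  # wider than the grid
        with pytest.warns(UserWarning, match="truncated"):
            beam_widths(f, -6.0, "lateral")

    def test_measured_nominal_width(self, nominal_field_1mm):
        """The simulated nominal focus is ~5 mm wide laterally and longer
        axially than laterally (cigar shape)."""
        wl = beam_widths(nominal_field_1mm, -6.0, "lateral")
        wa = beam_widths(nominal_field_1mm, -6.0, "axial")
        assert 3.0 < wl < 7.0
        assert wa > 3.0 * wl


class TestGratingRatio:
    def test_isolated_side_lobe(self):
        f = _gaussian_field()
        amp = f.amplitude.copy()
        amp[5, 20, 20] = 240.0  # side blob 15 mm off-axis laterally
        f2 = PressureField(f.grid_origin, f.spacing, amp)
        focus = (0.0, 0.0, 50.0)
        r = grating_lobe_ratio(f2, focus)
        assert r == pytest.approx(240.0 / 800.0, rel=0.01)

    def test_main_lobe_excluded_along_axis(self):
        """Energy on the beam axis (the elongated main lobe) is excluded even
        far from the focus."""
        f = _gaussian_field()
        amp = f.amplitude.copy()
        amp[20, 20, 2] = 790.0  # on-axis, 18 mm proximal to the focus
        f2 = PressureField(f.grid_origin, f.spacing, amp)
        r_with = grating_lobe_ratio(f2, (0.0, 0.0, 50.0))
        r_without = grating_lobe_ratio(f, (0.0, 0.0, 50.0))
        assert r_with == pytest.approx(r_without)

    def test_focus_outside_grid_rejected(self):
        f = _gaussian_field()
        with pytest.raises(ValueError):
            grating_lobe_ratio(f, (0.0, 0.0, 200.0))

    def test_nominal_focus_below_limit(self, nominal_field_2mm):
        r = grating_lobe_ratio(nominal_field_2mm, (0.0, 0.0, 50.0))
        assert 0.0 < r < 0.5


class TestIspta:
    def test_phase_1_1_identity(self):
        """Constant 510 kPa everywhere at Phase 1.1 duty gives the closed-form
        201 mW/cm^2."""
        amp = np.full((3, 3, 3), 510.0)
        f = PressureField((0, 0, 0), 1.0, amp)
        plan = phase_1_1_plan()
        tl = build_timeline(plan)
        m, peak = ispta_map([f], tl, Medium())
        assert peak == pytest.approx(pnp_to_isppa(510.0) * 1000.0 * 0.025,
                                     rel=1e-6)
        assert peak == pytest.approx(201.0, abs=0.5)

    def test_grid_mismatch_rejected(self):
        f1 = PressureField((0, 0, 0), 1.0, np.ones((3, 3, 3)))
        f2 = PressureField((1, 0, 0), 1.0, np.ones((3, 3, 3)))
        tl = build_timeline(phase_1_2_plan(), "interleaved")
        with pytest.raises(ValueError):
            ispta_map([f1, f2] * 3, tl)[0]

    def test_too_few_fields_rejected(self):
        f1 = PressureField((0, 0, 0), 1.0, np.ones((3, 3, 3)))
        tl = build_timeline(phase_1_2_plan(), "interleaved")
        with pytest.raises(ValueError):
            ispta_map([f1], tl)


class TestDistortionAndReport:
    def test_identical_fields_zero_offset(self):
        f = _gaussian_field()
        offset, dw = focal_distortion(f, f)
        np.testing.assert_allclose(offset, 0.0, atol=1e-9)
        np.testing.assert_allclose(dw, 0.0, atol=1e-9)

    def test_shifted_field_detected(self):
        f = _gaussian_field()
        shifted = PressureField(f.grid_origin, f.spacing,
                                np.roll(f.amplitude, 3, axis=2))
        offset, _ = focal_distortion(f, shifted)
        assert offset[2] == pytest.approx(3.0, abs=0.2)

    def test_report_json(self):
        rep = DoseReport(pnp_kpa=510.0, isppa_w_cm2=8.04, ispta_mw_cm2=201.0,
                         mi=0.806, tic=0.3, power_mw=60.0,
                         beamwidths_mm={(-6, "lateral"): 5.0})
        d = rep.to_dict()
        assert d["beamwidths_mm"]["-6dB_lateral"] == 5.0
        assert "201" in rep.to_json()
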