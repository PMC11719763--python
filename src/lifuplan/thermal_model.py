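"""Focal tissue heating via the Pennes bioheat equation.

dT/dt = kappa * lap(T) + Q/(rho C) - w (T - T0)

with volumetric heat deposition Q = 2 * alpha_Np * I while a pulse is on at
a given focus. The solver is an explicit finite-difference scheme on the
intensity grid, stepping through the pulse timeline segment by segment and
respecting the diffusion stability limit. Because the equation is linear,
the heating of a multi-focus sequence equals the superposition of each
focus's own excitation history — a property used for fast sequence design
and kept here as a regression check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ThermalStabilityError
from .sequence import Timeline

NEPER_PER_DB = math.log(10.0) / 20.0


@dataclass(frozen=True)
class TissueThermalParams:
    """Thermal properties of soft tissue.

    conductivity W/m/degC, volumetric heat capacity J/m^3/degC, perfusion
    rate 1/s (0 disables the perfusion sink), acoustic attenuation
    dB/cm/MHz used to convert intensity into heat deposition.
    """

    conductivity_w_m_c: float = 0.52
    rho_c_j_m3_c: float = 3.6e6
    perfusion_per_s: float = 0.0
    attenuation_db_cm_mhz: float = 0.3

    @property
    def diffusivity_m2_s(self) -> float:
        return self.conductivity_w_m_c / self.rho_c_j_m3_c

    def absorption_np_per_m(self, frequency_khz: float) -> float:
        return (self.attenuation_db_cm_mhz * (frequency_khz / 1000.0)
                * NEPER_PER_DB * 100.0)


@dataclass(frozen=True)
class ThermalResult:
    """Temperature rise over checkpoint times (degC above baseline)."""

    checkpoint_times_s: np.ndarray
    temperature_rise: np.ndarray  # (n_checkpoints, nx, ny, nz)
    peak_rise_c: float
    time_of_peak_s: float

    def final(self) -> np.ndarray:
        return self.temperature_rise[-1]


def _laplacian(t: np.ndarray, out: np.ndarray) -> np.ndarray:
    """6-neighbour Laplacian (unit spacing) with zero-gradient boundaries."""
    out[...] = -6.0 * t
    out[1:, :, :] += t[:-1, :, :]
    out[:-1, :, :] += t[1:, :, :]
    out[0, :, :] += t[0, :, :]
    out[-1, :, :] += t[-1, :, :]
    out[:, 1:, :] += t[:, :-1, :]
    out[:, :-1, :] += t[:, 1:, :]
    out[:, 0, :] += t[:, 0, :]
    out[:, -1, :] += t[:, -1, :]
    out[:, :, 1:] += t[:, :, :-1]
    out[:, :, :-1] += t[:, :, 1:]
    out[:, :, 0] += t[:, :, 0]
    out[:, :, -1] += t[:, :, -1]
    return out


def _segments(timeline: Timeline, duration_s: float):
    """Yield (t_start, t_end, focus_index or None) covering [0, duration]."""
    on = timeline.duration_ms / 1000.0
    t = 0.0
    for start, focus in zip(timeline.start_times_s, timeline.focus_indices):
        if start >= duration_s:
            break
        if start > t:
            yield t, min(start, duration_s), None
            t = start
        end = min(start + on, duration_s)
        if end > t:
            yield t, end, int(focus)
            t = end
    if t < duration_s:
        yield t, duration_s, None


def simulate_heating(intensity_fields: list[np.ndarray], timeline: Timeline,
                     params: TissueThermalParams, duration_s: float,
                     spacing_mm: float, frequency_khz: float = 400.0,
                     n_checkpoints: int = 60,
                     max_dt_s: float | None = None,
                     stability_fraction: float = 0.8) -> ThermalResult:
    """Explicit Pennes bioheat simulation of a pulse sequence.

    ``intensity_fields`` holds the pulse-average intensity grid (W/m^2) of
    each focus; heat Q = 2 alpha I is deposited while that focus's pulse is
    on. Checkpoints are uniform over [0, duration] and always include the
    instant of peak heating tracking (the running voxelwise maximum is kept
    separately).
    """
    if duration_s > timeline.total_duration_s + 1e-9:
        raise ValueError("duration exceeds the timeline's total duration")
    shape = intensity_fields[0].shape
    for f in intensity_fields:
        if f.shape != shape:
            raise ValueError("intensity fields must share a grid")
    h = spacing_mm * 1.0e-3  # m
    kappa = params.diffusivity_m2_s
    dt_stable = h * h / (6.0 * kappa)
    dt_max = stability_fraction * dt_stable
    if max_dt_s is not None:
        if max_dt_s > dt_stable:
            raise ThermalStabilityError(
                f"time step {max_dt_s:.3g} s exceeds the diffusion stability "
                f"limit {dt_stable:.3g} s; use <= {dt_max:.3g} s")
        dt_max = max_dt_s

    alpha = params.absorption_np_per_m(frequency_khz)
    q_over_rhoc = [2.0 * alpha * f / params.rho_c_j_m3_c for f in intensity_fields]

    check_times = np.linspace(0.0, duration_s, n_checkpoints)
    checkpoints = np.zeros((n_checkpoints, *shape))
    t_grid = np.zeros(shape)
    lap = np.empty(shape)
    peak = 0.0
    t_peak = 0.0
    ci = 1 if n_checkpoints > 1 else 0
    now = 0.0
    for seg_start, seg_end, focus in _segments(timeline, duration_s):
        src = q_over_rhoc[focus] if focus is not None else None
        seg_len = seg_end - seg_start
        n_steps = max(int(math.ceil(seg_len / dt_max)), 1)
        dt = seg_len / n_steps
        for _ in range(n_steps):
            _laplacian(t_grid, lap)
            t_grid += dt * (kappa / (h * h)) * lap
            if src is not None:
                t_grid += dt * src
            if params.perfusion_per_s:
                t_grid -= dt * params.perfusion_per_s * t_grid
            now += dt
            m = float(t_grid.max())
            if m > peak:
                peak, t_peak = m, now
            while ci < n_checkpoints and check_times[ci] <= now + 1e-12:
                checkpoints[ci] = t_grid
                ci += 1
    while ci < n_checkpoints:
        checkpoints[ci] = t_grid
        ci += 1
    return ThermalResult(check_times, checkpoints, peak, t_peak)


def superposition_heating(intensity_fields: list[np.ndarray], timeline: Timeline,
                          params: TissueThermalParams, duration_s: float,
                          spacing_mm: float, frequency_khz: float = 400.0,
                          n_checkpoints: int = 60) -> ThermalResult:
    """Heating via per-focus simulations summed at shared checkpoints.

    Each focal location is simulated once with only its own excitations, and
    the differential temperature histories are superimposed — valid because
    the bioheat equation is linear in the heat source.
    """
    n_foci = max(timeline.n_foci, 1)
    total = None
    times = None
    for f in range(n_foci):
        sel = timeline.focus_indices == f
        sub = Timeline(
            start_times_s=timeline.start_times_s[sel],
            focus_indices=np.zeros(int(sel.sum()), dtype=int),
            duration_ms=timeline.duration_ms,
            total_duration_s=timeline.total_duration_s,
            n_foci=1,
        )
        res = simulate_heating([intensity_fields[f]], sub, params, duration_s,
                               spacing_mm, frequency_khz, n_checkpoints)
        if total is None:
            total = res.temperature_rise.copy()
            times = res.checkpoint_times_s
        else:
            total += res.temperature_rise
    peaks = total.reshape(total.shape[0], -1).max(axis=1)
    i = int(np.argmax(peaks))
    return ThermalResult(times, total, float(peaks[i]), float(times[i]))


def exposure_limit_check(result: ThermalResult, tic: float, duration_s: float,
                         max_rise_c: float = 2.0, max_duration_s: float = 600.0,
                         max_tic: float = 3.0) -> dict:
    """Check the heating/duration/TIC exposure limits.

    Fails if peak heating reaches ``max_rise_c``, the ultrasound time exceeds
    10 minutes, or the TIC is at or above 3.
    """
    failures = []
    if result.peak_rise_c >= max_rise_c:
        failures.append(
            f"peak temperature rise {result.peak_rise_c:.2f} degC >= "
            f"{max_rise_c} degC")
    if duration_s > max_duration_s:
        failures.append(f"duration {duration_s:.0f} s > {max_duration_s:.0f} s")
    if tic >= max_tic:
        failures.append(f"TIC {tic:.2f} at or above {max_tic}")
    return {
        "passed": not failures,
        "failures": failures,
        "peak_rise_c": result.peak_rise_c,
        "tic": tic,
        "duration_s": duration_s,
    }
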