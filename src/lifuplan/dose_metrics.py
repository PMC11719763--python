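"""Exposure and safety metrics.

Conventions follow the standard diagnostic-ultrasound definitions:

* ``I_SPPA = p^2 / (2 rho c)`` — plane-wave pulse-average intensity from the
  focal peak negative pressure, with soft-tissue density and sound speed.
* ``MI = PNP[MPa] / sqrt(f[MHz])`` — free-field (non-derated) mechanical
  index.
* ``I_SPTA`` — voxelwise sum of per-focus intensities weighted by each
  focus's fraction of wall time; the spatial peak is the reported value.
* ``TIC = W / (D * C_TIC)`` — thermal index of the cranium from the
  time-averaged emitted acoustic power W (mW), the equivalent aperture
  diameter D (cm), and the normalization C_TIC = 40 mW/cm.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .array_model import ArrayGeometry
from .field_solver import SOFT_TISSUE, Medium, PressureField, Solution
from .sequence import Timeline

AXES = {"lateral": 0, "elevation": 1, "axial": 2}


@dataclass(frozen=True)
class TICConstants:
    """Equivalent aperture diameter (cm) and TIC normalization (mW/cm)."""

    d_eq_cm: float = 5.31
    c_tic_mw_per_cm: float = 40.0


@dataclass
class DoseReport:
    """All exposure/safety metrics for a plan at a given focus."""

    pnp_kpa: float
    isppa_w_cm2: float
    ispta_mw_cm2: float
    mi: float
    tic: float
    power_mw: float
    beamwidths_mm: dict = field(default_factory=dict)  # (level_db, axis) -> mm
    grating_ratio: float = float("nan")
    focal_centroid_mm: tuple = (0.0, 0.0, 0.0)
    focal_offset_mm: tuple = (0.0, 0.0, 0.0)

    def to_dict(self) -> dict:
        d = {
            "pnp_kpa": self.pnp_kpa,
            "isppa_w_cm2": self.isppa_w_cm2,
            "ispta_mw_cm2": self.ispta_mw_cm2,
            "mi": self.mi,
            "tic": self.tic,
            "power_mw": self.power_mw,
            "grating_ratio": self.grating_ratio,
            "focal_centroid_mm": list(self.focal_centroid_mm),
            "focal_offset_mm": list(self.focal_offset_mm),
            "beamwidths_mm": {f"{lvl}dB_{ax}": v
                              for (lvl, ax), v in self.beamwidths_mm.items()},
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def pnp_to_isppa(pnp_kpa: float, density: float = SOFT_TISSUE["density"],
                 sound_speed: float = SOFT_TISSUE["sound_speed"]) -> float:
    """Pulse-average intensity (W/cm^2) from peak negative pressure (kPa)."""
    p = pnp_kpa * 1.0e3  # Pa
    return p * p / (2.0 * density * sound_speed) / 1.0e4


def mechanical_index(pnp_kpa: float, frequency_khz: float) -> float:
    """MI = PNP[MPa] / sqrt(f[MHz]) (free-field, non-derated)."""
    if frequency_khz <= 0:
        raise ValueError("frequency must be positive")
    return (pnp_kpa / 1.0e3) / math.sqrt(frequency_khz / 1.0e3)


def thermal_index_cranium(power_mw: float,
                          constants: TICConstants = TICConstants()) -> float:
    """TIC from time-averaged acoustic power (mW)."""
    if power_mw < 0:
        raise ValueError("power must be non-negative")
    return power_mw / (constants.d_eq_cm * constants.c_tic_mw_per_cm)


def acoustic_power(solution: Solution, geom: ArrayGeometry,
                   timeline_duty: float = 1.0,
                   density: float = SOFT_TISSUE["density"],
                   sound_speed: float = SOFT_TISSUE["sound_speed"]) -> float:
    """Time-averaged emitted acoustic power, mW.

    Plane-wave power density at each element face, apod^2 p^2/(2 rho c),
    times element area and the sequence duty fraction.
    """
    p = solution.source_pressure_kpa * 1.0e3  # Pa
    intensity = (solution.apodization**2).sum() * p * p / (2 * density * sound_speed)
    area_m2 = geom.element_area_mm2 * 1.0e-6
    return intensity * area_m2 * timeline_duty * 1.0e3


def sequence_power(per_focus_pressures_kpa, geom: ArrayGeometry,
                   timeline: Timeline, pulse_duty_per_focus=None,
                   apodization: np.ndarray | None = None) -> float:
    """Sequence-averaged emitted power (mW) for a multi-focus solution.

    ``per_focus_pressures_kpa`` gives the scaled source pressure per focus;
    each focus contributes in proportion to its fraction of wall time.
    """
    fracs = timeline.focus_time_fractions()
    apod = (np.ones(geom.n_active) if apodization is None
            else np.asarray(apodization, float))
    total = 0.0
    for p_kpa, frac in zip(np.atleast_1d(per_focus_pressures_kpa), fracs):
        sol = Solution(delays_us=np.zeros(geom.n_active), apodization=apod,
                       source_pressure_kpa=float(p_kpa))
        total += acoustic_power(sol, geom, timeline_duty=float(frac))
    return total


def ispta_map(per_focus_fields: list[PressureField], timeline: Timeline,
              medium: Medium | None = None) -> tuple[np.ndarray, float]:
    """Voxelwise time-average intensity map (mW/cm^2) and its spatial peak."""
    if medium is None:
        medium = Medium()
    grids = {(tuple(f.grid_origin), f.spacing, f.amplitude.shape)
             for f in per_focus_fields}
    if len(grids) != 1:
        raise ValueError("per-focus fields must share one grid")
    fracs = timeline.focus_time_fractions()
    if timeline.n_foci > len(per_focus_fields):
        raise ValueError("timeline references more foci than fields given")
    rho = medium.reference_density
    c = medium.reference_sound_speed
    out = np.zeros(per_focus_fields[0].amplitude.shape)
    for f, frac in zip(per_focus_fields, fracs):
        p = f.amplitude * 1.0e3  # Pa
        out += (p * p / (2 * rho * c)) * frac
    out *= 1.0e3 / 1.0e4  # W/m^2 -> mW/cm^2
    return out, float(out.max())


def _profile_width(x: np.ndarray, values: np.ndarray, peak_index: int,
                   threshold: float) -> float:
    """Full width of the connected >= threshold run around the peak along a
    sampled line, with linear interpolation at the crossings."""
    n = values.size
    i = peak_index
    lo = i
    while lo > 0 and values[lo - 1] >= threshold:
        lo -= 1
    hi = i
    while hi < n - 1 and values[hi + 1] >= threshold:
        hi += 1
    truncated = False
    if lo == 0 and values[0] >= threshold:
        left = x[0]
        truncated = True
    else:
        f = (values[lo] - threshold) / (values[lo] - values[lo - 1])
        left = x[lo] - f * (x[lo] - x[lo - 1])
    if hi == n - 1 and values[-1] >= threshold:
        right = x[-1]
        truncated = True
    else:
        f = (values[hi] - threshold) / (values[hi] - values[hi + 1])
        right = x[hi] + f * (x[hi + 1] - x[hi])
    if truncated:
        warnings.warn("beamwidth level region touches the grid boundary; "
                      "width is truncated", stacklevel=3)
    return float(right - left)


def beam_widths(field: PressureField, level_db: float = -6.0,
                axis: str = "lateral") -> float:
    """Full width (mm) of the pressure focus at ``level_db`` along ``axis``.

    Measured along the grid line through the global amplitude maximum; the
    width spans the connected region where amplitude >= peak * 10^(level/20).
    """
    a = field.amplitude
    peak = a.max()
    if peak <= 0:
        raise ValueError("field must have a positive global maximum")
    # ties (e.g. a symmetric focus straddling two grid points) are fine:
    # any maximal point lies on the same level set, so take the first
    idx = np.unravel_index(int(np.argmax(a)), a.shape)
    ax = AXES[axis] if isinstance(axis, str) else int(axis)
    sl = list(idx)
    sl[ax] = slice(None)
    line = a[tuple(sl)]
    coords = field.grid_origin[ax] + field.spacing * np.arange(a.shape[ax])
    threshold = peak * 10.0 ** (-abs(level_db) / 20.0)
    return _profile_width(coords, line, idx[ax], threshold)


def grating_lobe_ratio(field: PressureField, focus, exclusion_radius: float = 10.0,
                       near_field_mm: float = 10.0) -> float:
    """Peak amplitude outside the main-lobe exclusion region relative to the
    focus amplitude.

    The focus is cigar-shaped (its axial extent far exceeds its lateral
    width), so the exclusion region is a tube of radius ``exclusion_radius``
    around the beam axis through the focus — this removes the whole main
    lobe while keeping laterally displaced grating lobes in the search. The
    first ``near_field_mm`` from the array face are also excluded.
    """
    focus = np.asarray(focus, float)
    grid = field.grid
    if not grid.contains(focus):
        raise ValueError("focus must lie inside the field grid")
    pts = grid.points().reshape(*grid.shape, 3)
    axis = focus / np.linalg.norm(focus)  # beam axis from the array center
    rel = pts - focus
    along = rel @ axis
    perp2 = (rel * rel).sum(axis=-1) - along**2
    mask = (perp2 > exclusion_radius**2) & (pts[..., 2] >= near_field_mm)
    amp_focus = field.amplitude_at(focus)
    if not mask.any():
        return 0.0
    side = float(field.amplitude[mask].max())
    return side / amp_focus if amp_focus > 0 else float("inf")


def _level_region_centroid(field: PressureField, level_db: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude-weighted centroid of the connected level region around the
    global peak (6-connectivity). Returns (centroid mm, region mask)."""
    a = field.amplitude
    peak_idx = np.unravel_index(int(np.argmax(a)), a.shape)
    threshold = a.max() * 10.0 ** (-abs(level_db) / 20.0)
    above = a >= threshold
    labels, _ = ndimage.label(above)  # default structure = 6-connectivity
    region = labels == labels[peak_idx]
    w = a * region
    idx = np.indices(a.shape, dtype=float)
    centroid_vox = np.array([(idx[i] * w).sum() / w.sum() for i in range(3)])
    centroid = field.grid_origin + field.spacing * centroid_vox
    return centroid, region


def focal_distortion(field_ref: PressureField, field_test: PressureField,
                     level_db: float = -6.0) -> tuple[np.ndarray, np.ndarray]:
    """Offset (mm) of the test focus centroid from the reference one, and
    per-axis beamwidth change (mm) at ``level_db``."""
    if field_ref.amplitude.shape != field_test.amplitude.shape:
        raise ValueError("fields must share a grid")
    c_ref, _ = _level_region_centroid(field_ref, level_db)
    c_test, _ = _level_region_centroid(field_test, level_db)
    widths = np.array([
        beam_widths(field_test, level_db, ax) - beam_widths(field_ref, level_db, ax)
        for ax in ("lateral", "elevation", "axial")
    ])
    return c_test - c_ref, widths
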