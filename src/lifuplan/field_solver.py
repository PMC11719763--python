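"""Steering delays and steady-state acoustic field simulation.

The solver is a monochromatic Rayleigh-Sommerfeld point summation: each
square element face is subdivided into a sub-element quadrature grid and
every patch radiates as a baffled point source. At the sequence's burst
lengths (thousands of cycles) the field is effectively continuous-wave, so a
single-frequency solution captures the steady-state pressure magnitude.

Heterogeneous media use a straight-ray phase screen: per element-to-voxel
ray the solver accumulates attenuation and travel-time (phase) corrections
by a midpoint line integral through the material maps, and zeroes rays that
cross air. Refraction and multiple scattering are neglected; the model
reduces exactly to the homogeneous solver on a uniform soft-tissue map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .array_model import ArrayGeometry, element_target_distances
from .exceptions import InvalidTargetError, UnreachableTargetError

#: Soft-tissue acoustic reference properties.
SOFT_TISSUE = {"sound_speed": 1540.0, "density": 1050.0, "attenuation": 0.3}

#: Material acoustic properties (speed m/s, density kg/m^3, attenuation
#: dB/cm/MHz), indexed by segmentation label.
MATERIALS = {
    "air": {"sound_speed": 344.0, "density": 1.25, "attenuation": 7.5},
    "soft_tissue": dict(SOFT_TISSUE),
    "skull": {"sound_speed": 2800.0, "density": 1900.0, "attenuation": 6.0},
    "water": {"sound_speed": 1500.0, "density": 1000.0, "attenuation": 0.0022},
    "coupling_pad": {"sound_speed": 1420.0, "density": 1000.0, "attenuation": 1.0},
}

#: Label integers used in phantom / segmentation grids.
LABELS = {"air": 0, "soft_tissue": 1, "skull": 2, "water": 3, "coupling_pad": 4}

NEPER_PER_DB = math.log(10.0) / 20.0


@dataclass(frozen=True)
class Medium:
    """Acoustic medium: homogeneous scalars or voxel maps on a regular grid.

    ``attenuation`` is in dB/cm/MHz; voxel maps must share shape and live on
    the grid given by ``grid_origin``/``spacing`` (transducer-frame mm).
    """

    sound_speed: object = SOFT_TISSUE["sound_speed"]
    density: object = SOFT_TISSUE["density"]
    attenuation: object = SOFT_TISSUE["attenuation"]
    grid_origin: np.ndarray | None = None
    spacing: float | None = None

    def __post_init__(self):
        for name in ("sound_speed", "density", "attenuation"):
            v = getattr(self, name)
            if np.any(np.asarray(v) <= 0) and name != "attenuation":
                raise ValueError(f"{name} must be positive")
        if self.is_map:
            shapes = {np.shape(self.sound_speed), np.shape(self.density),
                      np.shape(self.attenuation)}
            if len(shapes) != 1:
                raise ValueError("voxel-map property grids must share shape")
            if self.grid_origin is None or self.spacing is None:
                raise ValueError("voxel-map medium needs grid_origin and spacing")

    @property
    def is_map(self) -> bool:
        return np.ndim(self.sound_speed) == 3

    @property
    def reference_sound_speed(self) -> float:
        return SOFT_TISSUE["sound_speed"] if self.is_map else float(self.sound_speed)

    @property
    def reference_density(self) -> float:
        return SOFT_TISSUE["density"] if self.is_map else float(self.density)

    @classmethod
    def from_labels(cls, labels: np.ndarray, grid_origin, spacing: float) -> "Medium":
        """Build voxel property maps from a material-label grid."""
        names = {v: k for k, v in LABELS.items()}
        c = np.empty(labels.shape)
        rho = np.empty(labels.shape)
        att = np.empty(labels.shape)
        for value in np.unique(labels):
            props = MATERIALS[names[int(value)]]
            sel = labels == value
            c[sel] = props["sound_speed"]
            rho[sel] = props["density"]
            att[sel] = props["attenuation"]
        return cls(c, rho, att, np.asarray(grid_origin, float), float(spacing))


@dataclass(frozen=True)
class GridSpec:
    """Regular axis-aligned simulation lattice in the transducer frame."""

    origin: np.ndarray  # mm, center of voxel (0,0,0)
    spacing: float  # mm, isotropic
    shape: tuple  # (nx, ny, nz)

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if min(self.shape) < 1:
            raise ValueError("empty grid")

    @classmethod
    def from_bounds(cls, lo, hi, spacing: float) -> "GridSpec":
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        shape = np.floor((hi - lo) / spacing + 0.5).astype(int) + 1
        return cls(lo, spacing, tuple(shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> tuple:
        return tuple(self.origin[i] + self.spacing * np.arange(self.shape[i])
                     for i in range(3))

    def points(self) -> np.ndarray:
        """All voxel centers, shape (n_voxels, 3), C order."""
        ax = self.axes()
        g = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    def contains(self, point) -> bool:
        p = np.asarray(point, float)
        lo = self.origin - self.spacing / 2
        hi = self.origin + self.spacing * (np.array(self.shape) - 0.5)
        return bool(np.all(p >= lo) and np.all(p <= hi))


@dataclass(frozen=True)
class PressureField:
    """Steady-state pressure magnitude (kPa) on a regular grid, with optional
    phase (radians)."""

    grid_origin: np.ndarray
    spacing: float
    amplitude: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "grid_origin",
                           np.asarray(self.grid_origin, float).reshape(3))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_origin, self.spacing, self.amplitude.shape)

    def amplitude_at(self, point) -> float:
        """Trilinearly interpolated amplitude at a transducer-frame point."""
        idx = (np.asarray(point, float) - self.grid_origin) / self.spacing
        val = ndimage.map_coordinates(self.amplitude, idx.reshape(3, 1),
                                      order=1, mode="nearest")
        return float(val[0])

    def peak(self) -> tuple[float, np.ndarray]:
        """(peak amplitude, location mm of the global maximum voxel)."""
        flat = int(np.argmax(self.amplitude))
        idx = np.unravel_index(flat, self.amplitude.shape)
        loc = self.grid_origin + self.spacing * np.asarray(idx, float)
        return float(self.amplitude[idx]), loc

    def scaled(self, factor: float) -> "PressureField":
        return replace(self, amplitude=self.amplitude * factor)

    def save_npz(self, path) -> None:
        np.savez(path, grid_origin=self.grid_origin, spacing=self.spacing,
                 amplitude=self.amplitude,
                 phase=self.phase if self.phase is not None else np.empty(0))

    @classmethod
    def load_npz(cls, path) -> "PressureField":
        d = np.load(path)
        phase = d["phase"] if d["phase"].size else None
        return cls(d["grid_origin"], float(d["spacing"]), d["amplitude"], phase)

    def to_nifti(self):
        """NIfTI-1 image of the amplitude grid with a transducer-frame affine."""
        import nibabel as nib

        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[:3, 3] = self.grid_origin
        return nib.Nifti1Image(np.asarray(self.amplitude, np.float32), affine)


@dataclass(frozen=True)
class Solution:
    """Per-element drive realizing a plan: delays (µs), apodization weights,
    element surface pressure (kPa), and the proportional drive voltage."""

    delays_us: np.ndarray
    apodization: np.ndarray
    source_pressure_kpa: float = 1.0
    drive_voltage_v: float | None = None
    per_focus: tuple | None = None  # ((delays_us, apodization), ...) per focus

    def __post_init__(self):
        d = np.asarray(self.delays_us, float)
        a = np.asarray(self.apodization, float)
        if d.size and d.min() < -1e-12:
            raise ValueError("delays must be non-negative")
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("apodization weights must lie in [0, 1]")
        object.__setattr__(self, "delays_us", d)
        object.__setattr__(self, "apodization", a)

    def scaled(self, factor: float, kpa_per_volt: float = 25.0) -> "Solution":
        p = self.source_pressure_kpa * factor
        return replace(self, source_pressure_kpa=p, drive_voltage_v=p / kpa_per_volt)


def compute_delays(geom: ArrayGeometry, target, sound_speed: float = 1540.0
                   ) -> np.ndarray:
    """Time-of-flight focusing delays, µs; the farthest element fires first
    (delay 0 is assigned to the maximum path length)."""
    target = np.asarray(target, float).reshape(3)
    if target[2] <= 0:
        raise InvalidTargetError("target must lie in front of the array (z > 0)")
    d = element_target_distances(geom, target)  # mm
    c_mm_us = sound_speed / 1000.0  # mm/µs
    delays = (d.max() - d) / c_mm_us
    return delays


def uniform_solution(geom: ArrayGeometry, target, sound_speed: float = 1540.0,
                     source_pressure_kpa: float = 1.0) -> Solution:
    """Single-focus solution with uniform apodization."""
    return Solution(
        delays_us=compute_delays(geom, target, sound_speed),
        apodization=np.ones(geom.n_active),
        source_pressure_kpa=source_pressure_kpa,
    )


def _subelement_offsets(geom: ArrayGeometry, n_sub: int) -> np.ndarray:
    """Sub-element quadrature offsets (n_active, n_sub^2, 3) in mm."""
    side = geom.element_side
    u = (np.arange(n_sub) + 0.5) / n_sub - 0.5  # in units of element side
    uu, vv = np.meshgrid(u * side, u * side, indexing="ij")
    lat = geom.element_lateral_axes[:, None, :]
    elev = geom.element_elevation_axes()[:, None, :]
    return uu.ravel()[None, :, None] * lat + vv.ravel()[None, :, None] * elev


def _attenuation_np_per_mm(att_db_cm_mhz, frequency_khz: float):
    """dB/cm/MHz -> Np/mm at the operating frequency."""
    return np.asarray(att_db_cm_mhz) * (frequency_khz / 1000.0) * NEPER_PER_DB / 10.0


def transfer_matrix(geom: ArrayGeometry, points: np.ndarray, medium: Medium,
                    n_sub: int = 3, frequency_khz: float | None = None
                    ) -> np.ndarray:
    """Complex per-element transfer matrix H (n_points, n_active).

    H[v, e] is the complex pressure at point v produced by element e driven
    at unit surface pressure with zero delay: a sub-element-sampled
    Rayleigh-Sommerfeld sum exp(-ikd) k dS / (2 pi d) with soft-tissue-path
    attenuation applied along the element-center ray.
    """
    if frequency_khz is None:
        frequency_khz = geom.frequency_khz
    c = medium.reference_sound_speed
    # k [rad/mm] = 2 pi f[Hz] / c[m/s] / 1000 = 2 pi f[kHz] / c[m/s]
    k = 2.0 * math.pi * frequency_khz / c
    alpha = _attenuation_np_per_mm(float(medium.attenuation) if not medium.is_map
                                   else 0.0, frequency_khz)
    ds = (geom.element_side / n_sub) ** 2
    coeff = k * ds / (2.0 * math.pi)
    pts = np.asarray(points, float)
    offsets = _subelement_offsets(geom, n_sub)  # (n_el, n_sub^2, 3)
    H = np.empty((pts.shape[0], geom.n_active), dtype=np.complex128)
    for e in range(geom.n_active):
        sub = geom.element_centers[e] + offsets[e]  # (s, 3)
        d = np.linalg.norm(pts[:, None, :] - sub[None, :, :], axis=2)  # (v, s)
        He = (coeff * np.exp(-1j * k * d) / d).sum(axis=1)
        if not medium.is_map and alpha > 0:
            dc = np.linalg.norm(pts - geom.element_centers[e], axis=1)
            He *= np.exp(-alpha * dc)
        H[:, e] = He
    return H


def element_drive(solution: Solution, frequency_khz: float) -> np.ndarray:
    """Complex per-element drive weights at the carrier frequency."""
    omega = 2.0 * math.pi * frequency_khz / 1000.0  # rad/µs
    return (solution.apodization * solution.source_pressure_kpa
            * np.exp(-1j * omega * solution.delays_us))


def simulate_field(geom: ArrayGeometry, solution: Solution, medium: Medium,
                   grid: GridSpec, n_sub: int = 3) -> PressureField:
    """Continuous-wave pressure field of a solution on ``grid`` (kPa)."""
    lam = medium.reference_sound_speed / geom.frequency_khz  # mm
    if grid.spacing > lam / 2.0:
        warnings.warn(
            f"grid spacing {grid.spacing} mm exceeds lambda/2 = {lam/2:.2f} mm; "
            "the field may be spatially aliased", stacklevel=2)
    if medium.is_map:
        return propagate_heterogeneous(geom, solution, medium, grid, n_sub=n_sub)
    H = transfer_matrix(geom, grid.points(), medium, n_sub=n_sub)
    p = H @ element_drive(solution, geom.frequency_khz)
    amp = np.abs(p).reshape(grid.shape)
    phase = np.angle(p).reshape(grid.shape)
    return PressureField(grid.origin, grid.spacing, amp, phase)


def pressure_at_points(geom: ArrayGeometry, solution: Solution, medium: Medium,
                       points, n_sub: int = 3) -> np.ndarray:
    """Exact complex pressure (kPa) at arbitrary transducer-frame points."""
    pts = np.atleast_2d(np.asarray(points, float))
    H = transfer_matrix(geom, pts, medium, n_sub=n_sub)
    return H @ element_drive(solution, geom.frequency_khz)


def scale_to_pnp(field: PressureField, solution: Solution, target,
                 requested_pnp_kpa: float, kpa_per_volt: float = 25.0
                 ) -> tuple[float, Solution, PressureField]:
    """Scale drive and field so the target point reaches the requested PNP.

    Voltage is assumed proportional to surface pressure (linear medium), so a
    single scale multiplies source pressure, drive voltage, and the whole
    field.
    """
    amp = field.amplitude_at(target)
    if amp <= 0:
        raise UnreachableTargetError(
            f"zero amplitude at target {np.asarray(target).tolist()} (blocked)")
    scale = requested_pnp_kpa / amp
    return scale, solution.scaled(scale, kpa_per_volt), field.scaled(scale)


def _ray_line_integrals(geom: ArrayGeometry, medium: Medium, points: np.ndarray,
                        step_mm: float = 0.5, element_index: int | None = None):
    """Midpoint line integrals from element centers to each point.

    Returns (attenuation_np, phase_delay_rad_correction, blocked) arrays of
    shape (n_points,) for one element, or a generator over elements. The
    quadrature step divides each ray length exactly, so integrals over a
    uniform map are exact.
    """
    c_map = np.asarray(medium.sound_speed, float)
    att_np_mm = _attenuation_np_per_mm(np.asarray(medium.attenuation, float),
                                       geom.frequency_khz)
    inv_c = 1.0 / c_map
    c_ref = medium.reference_sound_speed
    omega_us = 2.0 * math.pi * geom.frequency_khz / 1000.0  # rad/µs
    origin = np.asarray(medium.grid_origin, float)
    sp = float(medium.spacing)
    air_mask = (c_map < 500.0).astype(float)

    def one(e: int):
        src = geom.element_centers[e]
        vec = points - src  # (n, 3)
        length = np.linalg.norm(vec, axis=1)
        n_steps = np.maximum(np.ceil(length / step_mm).astype(int), 1)
        n_max = int(n_steps.max())
        # midpoint fractions per ray, padded to n_max with NaN-free repeats
        t = (np.arange(n_max)[None, :] + 0.5) / n_steps[:, None]  # (n, n_max)
        valid = np.arange(n_max)[None, :] < n_steps[:, None]
        t = np.where(valid, t, 0.5)
        samp = src + t[..., None] * vec[:, None, :]  # (n, n_max, 3)
        idx = ((samp - origin) / sp).reshape(-1, 3).T
        ds = (length / n_steps)[:, None]

        def integ(grid):
            vals = ndimage.map_coordinates(grid, idx, order=1, mode="nearest")
            vals = vals.reshape(points.shape[0], n_max)
            return (np.where(valid, vals, 0.0) * ds).sum(axis=1)

        att = integ(att_np_mm)
        # inv_c is s/m; ds is mm, so the integral is in units of 1e-3 s·mm/m
        # = ms; multiply by 1000 for µs.
        travel_us = integ(inv_c) * 1000.0
        phase = omega_us * (travel_us - length / (c_ref / 1000.0))
        air_hit = integ(air_mask) > 0.0
        return att, phase, air_hit

    if element_index is not None:
        return one(element_index)
    return (one(e) for e in range(geom.n_active))


def propagate_heterogeneous(geom: ArrayGeometry, solution: Solution,
                            medium: Medium, grid: GridSpec, n_sub: int = 3,
                            step_mm: float = 0.5) -> PressureField:
    """Straight-ray phase-screen field through a voxel material map (kPa).

    Per element-to-voxel ray, attenuation and travel-time are accumulated
    along the material map; rays crossing air contribute nothing. With a
    uniform soft-tissue map this reproduces the homogeneous solver exactly.
    """
    if not medium.is_map:
        raise ValueError("propagate_heterogeneous requires a voxel-map medium")
    pts = grid.points()
    H = transfer_matrix(geom, pts, medium, n_sub=n_sub)  # no attenuation inside
    drive = element_drive(solution, geom.frequency_khz)
    p = np.zeros(pts.shape[0], dtype=np.complex128)
    for e, (att, phase, air_hit) in enumerate(
            _ray_line_integrals(geom, medium, pts, step_mm=step_mm)):
        corr = np.exp(-att - 1j * phase)
        corr[air_hit] = 0.0
        p += H[:, e] * corr * drive[e]
    amp = np.abs(p).reshape(grid.shape)
    phase_grid = np.angle(p).reshape(grid.shape)
    return PressureField(grid.origin, grid.spacing, amp, phase_grid)
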