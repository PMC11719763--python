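"""Electronic steering-range mapping.

For every candidate target on a lattice, the mapper computes the focusing
delays, the simulated field, the drive scale required to reach the plan's
target pressure, the resulting thermal index of the cranium, and the
grating-lobe ratio. A candidate is *valid* when the grating-lobe peak stays
below 50% of the focal amplitude and the TIC stays below 3 — the two
criteria that bound safe electronic steering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_model import ArrayGeometry
from .dose_metrics import acoustic_power, thermal_index_cranium
from .exceptions import OutOfGridError
from .field_solver import GridSpec, Medium, Solution, transfer_matrix
from .sequence import Plan, build_timeline, time_average_duty

#: Candidate lattice bounds used to characterize the steerable volume
#: (lateral, elevation, axial), mm.
DEFAULT_CANDIDATE_BOUNDS = ((-12.5, 12.5), (-20.0, 10.0), (40.0, 60.0))
DEFAULT_CANDIDATE_SPACING = 2.5


@dataclass(frozen=True)
class SteeringMap:
    """Per-candidate steering diagnostics over a target lattice.

    ``axes`` are the lateral/elevation/axial candidate coordinates (mm);
    the diagnostic arrays are indexed [lateral, elevation, axial].
    """

    axes: tuple  # (lat, elev, ax) 1D arrays, mm
    required_scale: np.ndarray  # source kPa per kPa of requested PNP scale
    tic: np.ndarray
    grating_ratio: np.ndarray
    valid: np.ndarray
    tic_limit: float = 3.0
    grating_limit: float = 0.5

    @property
    def shape(self) -> tuple:
        return tuple(len(a) for a in self.axes)

    def candidate_points(self) -> np.ndarray:
        g = np.meshgrid(*self.axes, indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    def revalidated(self, tic_limit: float | None = None,
                    grating_limit: float | None = None) -> "SteeringMap":
        """Re-derive the validity mask under different limits."""
        tl = self.tic_limit if tic_limit is None else tic_limit
        gl = self.grating_limit if grating_limit is None else grating_limit
        valid = (self.grating_ratio < gl) & (self.tic < tl)
        return SteeringMap(self.axes, self.required_scale, self.tic,
                           self.grating_ratio, valid, tl, gl)

    def valid_bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(extent per axis mm, center per axis mm) of the valid region."""
        pts = self.candidate_points()[self.valid.ravel()]
        if pts.size == 0:
            return np.zeros(3), np.full(3, np.nan)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return hi - lo, (hi + lo) / 2.0

    def lateral_extent_at_depth(self, depth_mm: float) -> float:
        """Lateral width (mm) of the valid region in the slice nearest to
        ``depth_mm`` along the axial axis."""
        kz = int(np.argmin(np.abs(self.axes[2] - depth_mm)))
        sl = self.valid[:, :, kz]
        if not sl.any():
            return 0.0
        lat = self.axes[0][np.nonzero(sl.any(axis=1))[0]]
        return float(lat.max() - lat.min())

    def to_dataframe(self) -> pd.DataFrame:
        pts = self.candidate_points()
        return pd.DataFrame({
            "lateral_mm": pts[:, 0], "elevation_mm": pts[:, 1],
            "axial_mm": pts[:, 2],
            "required_scale": self.required_scale.ravel(),
            "tic": self.tic.ravel(),
            "grating_ratio": self.grating_ratio.ravel(),
            "valid": self.valid.ravel(),
        })

    def valid_mask_nifti(self):
        import nibabel as nib

        spacing = [float(a[1] - a[0]) if len(a) > 1 else 1.0 for a in self.axes]
        affine = np.diag(spacing + [1.0])
        affine[:3, 3] = [a[0] for a in self.axes]
        return nib.Nifti1Image(self.valid.astype(np.uint8), affine)

    @classmethod
    def from_box(cls, bounds=DEFAULT_CANDIDATE_BOUNDS,
                 spacing: float = DEFAULT_CANDIDATE_SPACING) -> "SteeringMap":
        """Geometric surrogate map marking every lattice point valid.

        Useful as a fast pre-screen (e.g. during virtual fitting) when only
        the lattice bounds matter, before a full physical map is computed.
        """
        axes = tuple(np.arange(lo, hi + spacing / 2, spacing) for lo, hi in bounds)
        shape = tuple(len(a) for a in axes)
        ones = np.ones(shape)
        return cls(axes, ones, np.zeros(shape), np.zeros(shape),
                   np.ones(shape, dtype=bool))


def candidate_axes(bounds=DEFAULT_CANDIDATE_BOUNDS,
                   spacing: float = DEFAULT_CANDIDATE_SPACING) -> tuple:
    return tuple(np.arange(lo, hi + spacing / 2, spacing) for lo, hi in bounds)


def default_field_grid(spacing: float = 2.0) -> GridSpec:
    """Field-evaluation lattice wide enough to capture grating lobes for
    steering anywhere on the default candidate grid."""
    return GridSpec.from_bounds((-60.0, -60.0, 4.0), (60.0, 52.0, 72.0), spacing)


def map_steering(geom: ArrayGeometry, plan: Plan,
                 candidate_grid: tuple | None = None,
                 medium: Medium | None = None,
                 field_grid: GridSpec | None = None,
                 n_sub: int = 3,
                 exclusion_radius: float = 10.0,
                 near_field_mm: float = 10.0,
                 chunk: int = 48) -> SteeringMap:
    """Evaluate steering validity over a lattice of candidate targets.

    For each candidate: compute delays, evaluate the unit-drive field on a
    shared transfer matrix, scale to the plan's PNP, derive TIC from the
    required time-averaged power, and measure the grating-lobe ratio outside
    a 10 mm exclusion ball (ignoring the first 10 mm of near field).
    """
    if medium is None:
        medium = Medium()
    if candidate_grid is None:
        candidate_grid = candidate_axes()
    if field_grid is None:
        field_grid = default_field_grid()
    axes = tuple(np.asarray(a, float) for a in candidate_grid)
    cand = np.column_stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")])
    n_cand = cand.shape[0]

    # one-time transfer matrices: field lattice and the candidate points
    vox = field_grid.points().astype(np.float32)
    H = transfer_matrix(geom, field_grid.points(), medium, n_sub=n_sub
                        ).astype(np.complex64)
    Hc = transfer_matrix(geom, cand, medium, n_sub=n_sub)

    omega = 2.0 * math.pi * geom.frequency_khz / 1000.0  # rad/µs
    c_mm_us = medium.reference_sound_speed / 1000.0
    dist = np.linalg.norm(cand[:, None, :] - geom.element_centers[None, :, :],
                          axis=2)  # (n_cand, n_el)
    delays = (dist.max(axis=1, keepdims=True) - dist) / c_mm_us  # µs
    drive = np.exp(-1j * omega * delays)  # unit source pressure, (n_cand, n_el)

    amp_target = np.abs((Hc * drive).sum(axis=1))  # kPa per kPa source
    required_scale = plan.pnp_kpa / amp_target

    timeline = build_timeline(
        plan, raster="interleaved" if plan.n_foci > 1 else "single")
    duty = time_average_duty(plan, timeline)
    tic = np.empty(n_cand)
    for i in range(n_cand):
        sol = Solution(delays_us=np.zeros(geom.n_active),
                       apodization=np.ones(geom.n_active),
                       source_pressure_kpa=float(required_scale[i]))
        tic[i] = thermal_index_cranium(acoustic_power(sol, geom, duty))

    # grating search excludes a tube around each candidate's beam axis (the
    # elongated main lobe) and the first 10 mm of near field
    grating = np.empty(n_cand)
    near_ok = vox[:, 2] >= near_field_mm
    drive64 = drive.astype(np.complex64)
    for s in range(0, n_cand, chunk):
        e = min(s + chunk, n_cand)
        P = np.abs(H @ drive64[s:e].T)  # (n_vox, m)
        c_chunk = cand[s:e].astype(np.float32)
        axis = c_chunk / np.linalg.norm(c_chunk, axis=1, keepdims=True)
        rel = vox[:, None, :] - c_chunk[None, :, :]
        along = (rel * axis[None, :, :]).sum(axis=2)
        perp2 = (rel * rel).sum(axis=2) - along**2
        mask = (perp2 > exclusion_radius**2) & near_ok[:, None]
        P[~mask] = 0.0
        grating[s:e] = P.max(axis=0) / amp_target[s:e]

    shape = tuple(len(a) for a in axes)
    tic = tic.reshape(shape)
    grating = grating.reshape(shape)
    valid = (grating < plan.max_grating_ratio) & (tic < plan.max_tic)
    return SteeringMap(axes, required_scale.reshape(shape), tic, grating,
                       valid, plan.max_tic, plan.max_grating_ratio)


def is_valid_target(smap: SteeringMap, target) -> tuple[bool, dict]:
    """Nearest-candidate validity lookup with boundary diagnostics."""
    target = np.asarray(target, float).reshape(3)
    idx = []
    for i, ax in enumerate(smap.axes):
        half = (ax[1] - ax[0]) / 2.0 if len(ax) > 1 else 0.5
        if target[i] < ax[0] - half or target[i] > ax[-1] + half:
            raise OutOfGridError(
                f"target axis {i} value {target[i]:.1f} mm outside mapped "
                f"range [{ax[0]}, {ax[-1]}]")
        idx.append(int(np.argmin(np.abs(ax - target[i]))))
    idx = tuple(idx)
    nearest = np.array([smap.axes[i][idx[i]] for i in range(3)])
    pts = smap.candidate_points()
    invalid_pts = pts[~smap.valid.ravel()]
    if invalid_pts.size:
        d_bound = float(np.min(np.linalg.norm(invalid_pts - target, axis=1)))
    else:
        d_bound = float("inf")
    info = {
        "nearest_index": idx,
        "nearest_candidate_mm": nearest,
        "distance_to_candidate_mm": float(np.linalg.norm(nearest - target)),
        "distance_to_invalid_mm": d_bound,
        "tic": float(smap.tic[idx]),
        "grating_ratio": float(smap.grating_ratio[idx]),
    }
    return bool(smap.valid[idx]), info
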