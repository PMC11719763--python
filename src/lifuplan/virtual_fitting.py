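"""Virtual transducer fitting: placement recommendation over the skin surface.

The skin is segmented by simple thresholding into a polar-coordinate surface
map about the head center. Candidate array positions form an angular grid
over the forehead (by default 10-40 degrees above the eye-line and -5 to
+25 degrees from the center-line toward the subject's left, in 3-degree
steps — 121 positions). At each candidate the local skin patch is fit to a
plane to estimate the surface normal; the array is placed along that normal,
offset by the coupling-pad thickness and tilted by the pad's wedge angle
(default 10 degrees downward). Candidates whose required steering falls
outside the valid steering range are excluded; the rest are filtered to the
lowest decile of blocked-element counts; the winner is the remaining
candidate closest to the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_model import ArrayGeometry, TransducerPose
from .exceptions import NoValidPlacementError, OutOfGridError
from .head_volume import HeadVolume
from .sequence import NOMINAL_FOCUS_MM
from .sinus_rays import detect_blocked, normalize_rays, trace_bundle
from .steering_limits import SteeringMap, is_valid_target

DEFAULT_ELEVATION_RANGE = (10.0, 40.0)
DEFAULT_AZIMUTH_RANGE = (-5.0, 25.0)
DEFAULT_ANGLE_STEP = 3.0


def angles_to_direction(azimuth_deg, elevation_deg) -> np.ndarray:
    """Unit direction(s) in RAS for polar angles about the head center.

    Azimuth 0 is the center-line (+y, anterior), positive toward the
    subject's left (-x); elevation is degrees above the eye-line (z = 0
    plane), positive superior.
    """
    az = np.deg2rad(np.asarray(azimuth_deg, float))
    el = np.deg2rad(np.asarray(elevation_deg, float))
    return np.stack([-np.sin(az) * np.cos(el), np.cos(az) * np.cos(el),
                     np.sin(el) * np.ones_like(az)], axis=-1)


@dataclass(frozen=True)
class SkinSurface:
    """Polar skin-surface map: radius from head center per (elev, azim) bin."""

    elevation_deg: np.ndarray
    azimuth_deg: np.ndarray
    radii_mm: np.ndarray  # (n_elev, n_azim); NaN where no surface found
    head_center: np.ndarray

    def points(self) -> np.ndarray:
        """Surface points (n_elev*n_azim, 3) in RAS mm (NaN radii dropped)."""
        ee, aa = np.meshgrid(self.elevation_deg, self.azimuth_deg, indexing="ij")
        dirs = angles_to_direction(aa.ravel(), ee.ravel())
        pts = self.head_center + dirs * self.radii_mm.ravel()[:, None]
        return pts[~np.isnan(self.radii_mm.ravel())]

    def radius_at(self, elevation_deg: float, azimuth_deg: float) -> float:
        i = int(np.argmin(np.abs(self.elevation_deg - elevation_deg)))
        j = int(np.argmin(np.abs(self.azimuth_deg - azimuth_deg)))
        return float(self.radii_mm[i, j])

    def patch_points(self, elevation_deg: float, azimuth_deg: float,
                     half_width_deg: float) -> np.ndarray:
        sel_e = np.abs(self.elevation_deg - elevation_deg) <= half_width_deg
        sel_a = np.abs(self.azimuth_deg - azimuth_deg) <= half_width_deg
        ee, aa = np.meshgrid(self.elevation_deg[sel_e], self.azimuth_deg[sel_a],
                             indexing="ij")
        r = self.radii_mm[np.ix_(sel_e, sel_a)].ravel()
        dirs = angles_to_direction(aa.ravel(), ee.ravel())
        pts = self.head_center + dirs * r[:, None]
        return pts[~np.isnan(r)]


@dataclass
class FitCandidate:
    """One candidate transducer placement and its figure-of-merit inputs."""

    elevation_deg: float
    azimuth_deg: float
    pose: TransducerPose
    steering_offset_mm: np.ndarray  # target (transducer frame) - nominal focus
    target_in_frame_mm: np.ndarray
    n_blocked: int = 0
    distance_to_target_mm: float = float("nan")
    steering_valid: bool = False


def segment_skin(volume: HeadVolume, threshold: float,
                 head_center=(0.0, 0.0, 0.0),
                 elevation_range=(-10.0, 60.0), azimuth_range=(-45.0, 45.0),
                 angle_step_deg: float = 1.5, r_max_mm: float = 130.0,
                 radial_step_mm: float = 0.5) -> SkinSurface:
    """Threshold-based skin surface extraction in polar coordinates.

    For each angular bin the radius of the outermost suprathreshold sample
    along the radial ray from the head center is recorded; rays with no
    suprathreshold sample get NaN (missing coverage).
    """
    elev = np.arange(elevation_range[0], elevation_range[1] + angle_step_deg / 2,
                     angle_step_deg)
    azim = np.arange(azimuth_range[0], azimuth_range[1] + angle_step_deg / 2,
                     angle_step_deg)
    center = np.asarray(head_center, float)
    r = np.arange(0.0, r_max_mm + radial_step_mm / 2, radial_step_mm)
    radii = np.full((elev.size, azim.size), np.nan)
    for i, e in enumerate(elev):
        dirs = angles_to_direction(azim, np.full(azim.size, e))  # (n_az, 3)
        pts = center + dirs[:, None, :] * r[None, :, None]  # (n_az, n_r, 3)
        vals = volume.sample(pts.reshape(-1, 3)).reshape(azim.size, r.size)
        above = vals >= threshold
        has = above.any(axis=1)
        # outermost suprathreshold sample
        outer = r.size - 1 - np.argmax(above[:, ::-1], axis=1)
        radii[i, has] = r[outer[has]]
    if np.isnan(radii).all():
        raise ValueError("no suprathreshold voxels found on any radial ray")
    return SkinSurface(elev, azim, radii, center)


def candidate_positions(elevation_range=DEFAULT_ELEVATION_RANGE,
                        azimuth_range=DEFAULT_AZIMUTH_RANGE,
                        step_deg: float = DEFAULT_ANGLE_STEP) -> list:
    """Angular candidate grid; the defaults give the 11 x 11 = 121 positions."""
    elev = np.arange(elevation_range[0], elevation_range[1] + step_deg / 2,
                     step_deg)
    azim = np.arange(azimuth_range[0], azimuth_range[1] + step_deg / 2, step_deg)
    return [(float(e), float(a)) for e in elev for a in azim]


def place_virtual_transducer(surface: SkinSurface, angles,
                             wedge_deg: float = 10.0,
                             pad_thickness_mm: float = 10.0,
                             patch_half_width_deg: float = 8.0
                             ) -> TransducerPose:
    """Pose of the array virtually placed on the skin at the given angles.

    The skin patch under the array footprint is fit to a plane (least
    squares); the array axial axis is the inward plane normal tilted
    ``wedge_deg`` downward (toward negative elevation, emulating the wedged
    coupling pad); the face center sits at the patch centroid offset outward
    by the pad thickness.
    """
    elevation_deg, azimuth_deg = angles
    pts = surface.patch_points(elevation_deg, azimuth_deg, patch_half_width_deg)
    if pts.shape[0] < 3:
        raise ValueError("fewer than 3 surface points under the array footprint")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[2]
    outward = angles_to_direction(azimuth_deg, elevation_deg)
    if np.dot(normal, outward) < 0:
        normal = -normal
    axial = -normal  # into the head
    # local frame before the wedge: lateral to subject's right, elev superior
    up = np.array([0.0, 0.0, 1.0])
    lateral = np.cross(up, axial)
    lateral /= np.linalg.norm(lateral)
    elev_axis = np.cross(axial, lateral)
    # wedge: rotate axial (and elevation axis) about the lateral axis so the
    # beam aims downward by wedge_deg
    w = np.deg2rad(wedge_deg)
    axial_w = np.cos(w) * axial - np.sin(w) * elev_axis
    elev_w = np.cos(w) * elev_axis + np.sin(w) * axial
    axes = np.column_stack([lateral, elev_w, axial_w])
    origin = centroid + normal * pad_thickness_mm
    return TransducerPose(origin, axes)


def evaluate_candidates(volume: HeadVolume, surface: SkinSurface, target_ras,
                        geom: ArrayGeometry, steering_map: SteeringMap,
                        angles_list=None, wedge_deg: float = 10.0,
                        pad_thickness_mm: float = 10.0,
                        ray_step_mm: float = 1.0) -> list:
    """Build and score every candidate placement."""
    if angles_list is None:
        angles_list = candidate_positions()
    target = np.asarray(target_ras, float)
    out = []
    for angles in angles_list:
        pose = place_virtual_transducer(surface, angles, wedge_deg,
                                        pad_thickness_mm)
        t_frame = pose.to_transducer(target)
        try:
            valid, _ = is_valid_target(steering_map, t_frame)
        except OutOfGridError:
            valid = False
        cand = FitCandidate(
            elevation_deg=angles[0], azimuth_deg=angles[1], pose=pose,
            steering_offset_mm=t_frame - np.asarray(NOMINAL_FOCUS_MM),
            target_in_frame_mm=t_frame,
            distance_to_target_mm=float(np.linalg.norm(target - pose.origin)),
            steering_valid=bool(valid),
        )
        if valid:
            bundle = normalize_rays(
                trace_bundle(volume, geom, pose, target, ray_step_mm))
            cand.n_blocked = int(detect_blocked(bundle).sum())
        out.append(cand)
    return out


def optimize_placement(candidates: list, decile: float = 10.0
                       ) -> tuple[FitCandidate, pd.DataFrame]:
    """Three-stage placement filter.

    1. drop steering-invalid candidates; 2. keep the lowest decile of
    blocked-element counts (nearest-rank percentile, so ties at the minimum
    all pass); 3. return the remaining candidate closest to the target.
    Distance ties break on smallest elevation angle, then smallest azimuth.
    """
    if not candidates:
        raise NoValidPlacementError("no candidates supplied")
    valid = [c for c in candidates if c.steering_valid]
    if not valid:
        raise NoValidPlacementError("all candidate placements are steering-invalid")
    counts = np.array([c.n_blocked for c in valid])
    cutoff = np.percentile(counts, decile, method="inverted_cdf")
    pool = [c for c in valid if c.n_blocked <= cutoff]
    best = min(pool, key=lambda c: (c.distance_to_target_mm, c.elevation_deg,
                                    c.azimuth_deg))
    report = pd.DataFrame({
        "elevation_deg": [c.elevation_deg for c in candidates],
        "azimuth_deg": [c.azimuth_deg for c in candidates],
        "steering_valid": [c.steering_valid for c in candidates],
        "n_blocked": [c.n_blocked for c in candidates],
        "distance_to_target_mm": [c.distance_to_target_mm for c in candidates],
        "selected": [c is best for c in candidates],
    })
    return best, report


def plot_fit_report(report: pd.DataFrame, ax=None):
    """Surface map of candidates: blocked counts, validity, and the winner."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = report[report.steering_valid]
    bad = report[~report.steering_valid]
    sc = ax.scatter(ok.azimuth_deg, ok.elevation_deg, c=ok.n_blocked,
                    cmap="viridis", s=60, label="steering-valid")
    ax.scatter(bad.azimuth_deg, bad.elevation_deg, c="red", marker="x", s=40,
               label="invalid steering")
    win = report[report.selected]
    ax.scatter(win.azimuth_deg, win.elevation_deg, facecolors="none",
               edgecolors="cyan", s=200, linewidths=2, label="optimized")
    ax.set_xlabel("azimuth (deg, + toward left)")
    ax.set_ylabel("elevation above eye-line (deg)")
    ax.legend(loc="best", fontsize=8)
    plt.colorbar(sc, ax=ax, label="blocked elements")
    return ax
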