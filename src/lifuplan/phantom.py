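"""Deterministic synthetic head phantoms with ground truth.

The phantom is an ellipsoidal head: a T1-bright scalp layer at the surface,
a skull shell of configurable thickness (intermediate intensity), a
soft-tissue brain interior, spherical air-filled sinus cavities embedded
against the inner skull surface, and air outside — emulating the contrast
structure
of a T1/PETRA head scan (bright soft tissue, intermediate bone, dark air)
without modelling MRI physics. Intensities are label means plus seeded
Gaussian noise, so identical specs and seeds give bit-identical volumes.

The generator also provides the independent geometric oracle for the
ray-tracing sinus detector: an element's path is truly blocked iff the
straight segment from the element to the target intersects a sinus sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .array_model import ArrayGeometry, TransducerPose
from .field_solver import LABELS
from .head_volume import HeadVolume

#: Label intensity means chosen so the ray normalization puts air near 0.02,
#: skull near 0.3 and white matter at 1.0 (only air falls below the 10%
#: blocked threshold, as on T1 contrast).
DEFAULT_INTENSITIES = {
    "air": (20.0, 20.0),
    "soft_tissue": (1000.0, 20.0),
    "skull": (300.0, 20.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast of a synthetic head.

    ``head_radii`` are the outer (skin) ellipsoid semi-axes (x lateral, y
    anterior-posterior, z superior-inferior), mm, centered at the RAS origin.
    A scalp layer sits at the surface, the skull shell directly beneath it.
    Sinus spheres must lie fully inside the outer surface.
    """

    head_radii: tuple = (70.0, 90.0, 80.0)
    scalp_thickness_mm: float = 4.0
    skull_thickness_mm: float = 6.0
    sinus_centers: tuple = ()
    sinus_radii: tuple = ()
    tissue_intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    voxel_size_mm: float = 2.0
    margin_mm: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if len(self.sinus_centers) != len(self.sinus_radii):
            raise ValueError("sinus_centers and sinus_radii lengths differ")
        radii = np.asarray(self.head_radii, float)
        dirs = _sphere_directions(256)
        for c, r in zip(self.sinus_centers, self.sinus_radii):
            c = np.asarray(c, float)
            worst = np.linalg.norm((c + r * dirs) / radii, axis=1).max()
            if worst > 1.0:
                raise ValueError(f"sinus at {c.tolist()} extends outside the head")


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def frontal_sinus_spec(sinus_radius_mm: float = 10.0, separation_mm: float = 26.0,
                       elevation_mm: float = 12.0, **kwargs) -> PhantomSpec:
    """Spec with a symmetric pair of frontal sinuses behind the brow,
    tangent to the inner skull surface."""
    base = PhantomSpec(**kwargs)
    ry = base.head_radii[1]
    y = ry - base.scalp_thickness_mm - base.skull_thickness_mm - sinus_radius_mm
    centers = ((-separation_mm / 2, y, elevation_mm),
               (separation_mm / 2, y, elevation_mm))
    return PhantomSpec(sinus_centers=centers,
                       sinus_radii=(sinus_radius_mm, sinus_radius_mm), **kwargs)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth geometry of a generated phantom."""

    spec: PhantomSpec
    masks: dict  # label name -> boolean grid

    def blocked_elements(self, geom: ArrayGeometry, pose: TransducerPose,
                         target_ras) -> np.ndarray:
        """Exact geometric oracle: element blocked iff its straight segment to
        the target intersects any sinus sphere."""
        starts = pose.to_ras(geom.element_centers)
        target = np.asarray(target_ras, float)
        blocked = np.zeros(geom.n_active, dtype=bool)
        for c, r in zip(self.spec.sinus_centers, self.spec.sinus_radii):
            blocked |= _segment_hits_sphere(starts, target, np.asarray(c, float), r)
        return blocked


def _segment_hits_sphere(p0: np.ndarray, p1, center: np.ndarray, radius: float
                         ) -> np.ndarray:
    """Vectorized segment-sphere intersection test (p0 may be (n, 3))."""
    p0 = np.atleast_2d(p0)
    p1 = np.asarray(p1, float)
    d = p1 - p0  # (n, 3)
    f = p0 - center
    a = (d * d).sum(axis=1)
    b = 2.0 * (f * d).sum(axis=1)
    c = (f * f).sum(axis=1) - radius**2
    disc = b * b - 4 * a * c
    hit = np.zeros(p0.shape[0], dtype=bool)
    ok = (disc >= 0) & (a > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = (-b - sq) / np.where(a > 0, 2 * a, 1.0)
    t2 = (-b + sq) / np.where(a > 0, 2 * a, 1.0)
    hit |= ok & (((t1 >= 0) & (t1 <= 1)) | ((t2 >= 0) & (t2 <= 1))
                 | ((t1 < 0) & (t2 > 1)))  # segment fully inside
    return hit


def make_head_phantom(spec: PhantomSpec = PhantomSpec()
                      ) -> tuple[HeadVolume, PhantomTruth]:
    """Generate the phantom volume (intensities + labels) and its truth."""
    radii = np.asarray(spec.head_radii, float)
    half = radii + spec.margin_mm
    v = spec.voxel_size_mm
    n = (np.ceil(2 * half / v)).astype(int) + 1
    axes = [(-(ni - 1) / 2 + np.arange(ni)) * v for ni in n]
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = [a[0] for a in axes]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")

    def _f(semi):
        return np.sqrt((gx / semi[0]) ** 2 + (gy / semi[1]) ** 2
                       + (gz / semi[2]) ** 2)

    f_outer = _f(radii)
    f_skull = _f(radii - spec.scalp_thickness_mm)
    f_inner = _f(radii - spec.scalp_thickness_mm - spec.skull_thickness_mm)

    labels = np.full(tuple(n), LABELS["air"], dtype=np.int16)
    labels[f_outer <= 1.0] = LABELS["soft_tissue"]  # scalp
    labels[f_skull <= 1.0] = LABELS["skull"]
    labels[f_inner <= 1.0] = LABELS["soft_tissue"]  # brain
    sinus_mask = np.zeros(tuple(n), dtype=bool)
    for c, r in zip(spec.sinus_centers, spec.sinus_radii):
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        sinus_mask |= d2 <= r * r
    labels[sinus_mask] = LABELS["air"]

    rng = np.random.default_rng(spec.seed)
    intensities = np.empty(tuple(n))
    name_by_label = {LABELS[k]: k for k in ("air", "soft_tissue", "skull")}
    for value, name in name_by_label.items():
        mean, sd = spec.tissue_intensities[name]
        sel = labels == value
        intensities[sel] = mean
    intensities += rng.normal(0.0, 1.0, size=tuple(n)) * np.where(
        labels == LABELS["air"], spec.tissue_intensities["air"][1],
        spec.tissue_intensities["soft_tissue"][1])
    np.clip(intensities, 0.0, None, out=intensities)

    volume = HeadVolume(intensities, affine, labels)
    masks = {
        "air": labels == LABELS["air"],
        "soft_tissue": labels == LABELS["soft_tissue"],
        "skull": labels == LABELS["skull"],
        "sinus": sinus_mask,
    }
    return volume, PhantomTruth(spec, masks)


def forehead_pose(spec: PhantomSpec, target_ras=(0.0, 40.0, 10.0),
                  elevation_deg: float = 20.0, azimuth_deg: float = 0.0,
                  standoff_mm: float = 10.0) -> TransducerPose:
    """Convenience pose: array on the phantom forehead aimed at the target.

    The array-face center sits on the outer ellipsoid surface along the
    (azimuth, elevation) direction, offset outward by ``standoff_mm`` (the
    coupling-pad thickness), with the axial axis aimed straight at the
    target.
    """
    radii = np.asarray(spec.head_radii, float)
    el = np.deg2rad(elevation_deg)
    az = np.deg2rad(azimuth_deg)
    direction = np.array([-np.sin(az) * np.cos(el), np.cos(az) * np.cos(el),
                          np.sin(el)])
    # radius of the ellipsoid along this direction
    r_dir = 1.0 / np.linalg.norm(direction / radii)
    origin = direction * (r_dir + standoff_mm)
    target = np.asarray(target_ras, float)
    axial = target - origin
    axial /= np.linalg.norm(axial)
    # lateral toward subject's right, elevation roughly superior
    lateral = np.cross(np.array([0.0, 0.0, 1.0]), axial)
    lateral /= np.linalg.norm(lateral)
    elev_axis = np.cross(axial, lateral)
    axes = np.column_stack([lateral, elev_axis, axial])
    return TransducerPose(origin, axes)
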