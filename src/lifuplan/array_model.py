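"""Geometry of the curved 2D matrix transducer array.

The transducer frame has its origin at the center of the array face, +x
lateral (along the columns), +y elevation (along the rows, superior when the
array is worn on the forehead), and +z axial, pointing into the head. The
array is cylindrically curved about the elevation axis: element centers lie
on a cylinder in the lateral-axial plane and their normals re-aim at the
cylinder axis, so the geometric (lateral) focus sits at
(0, 0, curvature_radius).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidGeometryError, InvalidTargetError

#: Default operating frequency, kHz.
DEFAULT_FREQUENCY_KHZ = 400.0
#: Default element pitch, mm.
DEFAULT_PITCH_MM = 4.1
#: Default cylindrical radius of curvature, mm.
DEFAULT_CURVATURE_MM = 50.0


@dataclass(frozen=True)
class TransducerPose:
    """Rigid pose of the transducer frame inside a volume's RAS frame.

    ``axes`` columns are the lateral, elevation and axial unit vectors
    expressed in RAS coordinates; ``origin`` is the array-face center in mm.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-8):
            raise InvalidGeometryError("pose axes must be orthonormal")
        if np.linalg.det(axes) < 0.99:
            raise InvalidGeometryError("pose axes must be right-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    def to_ras(self, points_t: np.ndarray) -> np.ndarray:
        """Map transducer-frame points (…, 3) to RAS mm."""
        pts = np.asarray(points_t, dtype=float)
        return pts @ self.axes.T + self.origin

    def to_transducer(self, points_ras: np.ndarray) -> np.ndarray:
        """Map RAS points (…, 3) into the transducer frame."""
        pts = np.asarray(points_ras, dtype=float)
        return (pts - self.origin) @ self.axes

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "axes": self.axes.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TransducerPose":
        return cls(np.asarray(d["origin"]), np.asarray(d["axes"]))

    @classmethod
    def identity(cls) -> "TransducerPose":
        return cls(np.zeros(3), np.eye(3))


@dataclass(frozen=True)
class ArrayGeometry:
    """Active-element geometry of the matrix array.

    All lengths are in millimeters, in the transducer frame. Only active
    (connected) elements are stored; ``rows``/``cols`` give each active
    element's grid cell.
    """

    element_centers: np.ndarray  # (n_active, 3)
    element_normals: np.ndarray  # (n_active, 3), unit, +z-facing
    element_lateral_axes: np.ndarray  # (n_active, 3) in-face lateral tangent
    pitch: float
    n_rows: int
    n_cols: int
    curvature_radius: float  # mm; inf for a flat array
    frequency_khz: float
    element_side: float
    active_mask: np.ndarray  # (n_rows, n_cols) bool
    rows: np.ndarray = field(repr=False, default=None)
    cols: np.ndarray = field(repr=False, default=None)

    @property
    def n_active(self) -> int:
        return self.element_centers.shape[0]

    @property
    def element_area_mm2(self) -> float:
        return self.element_side**2

    @property
    def active_area_cm2(self) -> float:
        return self.n_active * self.element_area_mm2 / 100.0

    @property
    def wavelength_mm(self) -> float:
        """Wavelength in soft tissue (1540 m/s) at the operating frequency."""
        return 1540.0 / self.frequency_khz  # (m/s)/(kHz) = mm

    @property
    def equivalent_aperture_diameter_cm(self) -> float:
        """Diameter of the disc with the same active area."""
        return 2.0 * math.sqrt(self.active_area_cm2 / math.pi)

    def element_elevation_axes(self) -> np.ndarray:
        return np.cross(self.element_normals, self.element_lateral_axes)

    def mirror_index_map(self) -> np.ndarray:
        """Permutation mapping each active element to its lateral mirror.

        Mirroring the lateral (x) coordinate of a target produces a distance
        vector that is this permutation of the original one.
        """
        lookup = {(r, c): i for i, (r, c) in enumerate(zip(self.rows, self.cols))}
        out = np.empty(self.n_active, dtype=int)
        for i, (r, c) in enumerate(zip(self.rows, self.cols)):
            out[i] = lookup[(r, self.n_cols - 1 - c)]
        return out

    def to_json(self) -> str:
        table = [
            {
                "id": int(i),
                "row": int(r),
                "col": int(c),
                "center": self.element_centers[i].tolist(),
                "normal": self.element_normals[i].tolist(),
            }
            for i, (r, c) in enumerate(zip(self.rows, self.cols))
        ]
        return json.dumps(
            {
                "pitch_mm": self.pitch,
                "n_rows": self.n_rows,
                "n_cols": self.n_cols,
                "curvature_radius_mm": None
                if math.isinf(self.curvature_radius)
                else self.curvature_radius,
                "frequency_khz": self.frequency_khz,
                "element_side_mm": self.element_side,
                "trim_corners": bool(not self.active_mask.all()),
                "elements": table,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArrayGeometry":
        d = json.loads(text)
        radius = d["curvature_radius_mm"]
        return build_array(
            pitch=d["pitch_mm"],
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            curvature_radius=math.inf if radius is None else radius,
            frequency_khz=d["frequency_khz"],
            trim_corners=d["trim_corners"],
            element_side=d["element_side_mm"],
        )


def build_array(
    pitch: float = DEFAULT_PITCH_MM,
    n_rows: int = 11,
    n_cols: int = 12,
    curvature_radius: float = DEFAULT_CURVATURE_MM,
    frequency_khz: float = DEFAULT_FREQUENCY_KHZ,
    trim_corners: bool = True,
    element_side: float | None = None,
) -> ArrayGeometry:
    """Construct the matrix-array geometry.

    The default parameters describe the 128-element array: an 11 x 12 grid at
    4.1 mm pitch with the four corner cells unconnected, cylindrically curved
    with a 50 mm radius in the lateral direction. The element pitch is
    preserved as arc length along the cylinder, so column spacing on the
    curved face equals the flat-grid pitch.
    """
    if pitch <= 0:
        raise InvalidGeometryError("pitch must be positive")
    if n_rows < 1 or n_cols < 1:
        raise InvalidGeometryError("n_rows and n_cols must be >= 1")
    if curvature_radius <= 0:
        raise InvalidGeometryError("curvature radius must be positive (or inf)")
    if element_side is None:
        element_side = pitch
    half_arc = (n_cols - 1) / 2.0 * pitch
    if math.isfinite(curvature_radius) and half_arc >= curvature_radius * math.pi / 2:
        raise InvalidGeometryError("array wraps beyond the cylinder quarter-arc")

    mask = np.ones((n_rows, n_cols), dtype=bool)
    if trim_corners and n_rows >= 2 and n_cols >= 2:
        mask[0, 0] = mask[0, -1] = mask[-1, 0] = mask[-1, -1] = False

    rows, cols = np.nonzero(mask)
    y = (rows - (n_rows - 1) / 2.0) * pitch
    s = (cols - (n_cols - 1) / 2.0) * pitch  # lateral arc length
    if math.isinf(curvature_radius):
        x = s
        z = np.zeros_like(s)
        nx = np.zeros_like(s)
        nz = np.ones_like(s)
    else:
        theta = s / curvature_radius
        x = curvature_radius * np.sin(theta)
        z = curvature_radius * (1.0 - np.cos(theta))
        nx = -np.sin(theta)
        nz = np.cos(theta)

    centers = np.column_stack([x, y, z])
    normals = np.column_stack([nx, np.zeros_like(nx), nz])
    lateral = np.column_stack([nz, np.zeros_like(nx), -nx])  # in-face tangent

    return ArrayGeometry(
        element_centers=centers,
        element_normals=normals,
        element_lateral_axes=lateral,
        pitch=float(pitch),
        n_rows=int(n_rows),
        n_cols=int(n_cols),
        curvature_radius=float(curvature_radius),
        frequency_khz=float(frequency_khz),
        element_side=float(element_side),
        active_mask=mask,
        rows=rows,
        cols=cols,
    )


def element_target_distances(geom: ArrayGeometry, target) -> np.ndarray:
    """Euclidean distance from every active element center to ``target`` (mm)."""
    target = np.asarray(target, dtype=float).reshape(3)
    if not np.all(np.isfinite(target)):
        raise InvalidTargetError("target must be finite")
    return np.linalg.norm(geom.element_centers - target, axis=1)
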