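"""Head volumes: NIfTI I/O, coordinate frames, resampling, and ray sampling.

All world coordinates are RAS millimeters with the voxel-center convention;
volumes loaded from disk are reoriented to the closest RAS-canonical axes.
Points outside a volume are treated as air.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .array_model import TransducerPose
from .exceptions import InvalidGeometryError
from .field_solver import GridSpec

#: Intensity assigned to space outside the scanned volume.
AIR_FILL_VALUE = 0.0


@dataclass
class HeadVolume:
    """Voxel intensities with a voxel-to-RAS affine and optional labels."""

    intensities: np.ndarray
    affine: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.affine = np.asarray(self.affine, float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise InvalidGeometryError("affine must be invertible")
        if self.labels is not None and self.labels.shape != self.intensities.shape:
            raise ValueError("labels must match intensity grid shape")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def voxel_to_ras(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def ras_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def sample(self, points_ras: np.ndarray, order: int = 1,
               fill: float = AIR_FILL_VALUE) -> np.ndarray:
        """Interpolated intensities at RAS points (air fill outside)."""
        vox = self.ras_to_voxel(np.atleast_2d(points_ras))
        return ndimage.map_coordinates(self.intensities, vox.T, order=order,
                                       mode="constant", cval=fill)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.intensities, np.float32),
                               self.affine)

    def save(self, path, labels_path=None) -> None:
        nib.save(self.to_nifti(), str(path))
        if labels_path is not None and self.labels is not None:
            nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine),
                     str(labels_path))


def load_volume(path, labels_path=None) -> HeadVolume:
    """Load a NIfTI-1 volume, reoriented to closest-canonical RAS."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    labels = None
    if labels_path is not None:
        limg = nib.as_closest_canonical(nib.load(str(labels_path)))
        labels = np.asarray(limg.dataobj).astype(np.int16)
    return HeadVolume(np.asarray(img.dataobj, dtype=float), img.affine, labels)


def to_transducer_frame(volume: HeadVolume, pose: TransducerPose,
                        grid: GridSpec) -> tuple[np.ndarray, np.ndarray | None]:
    """Resample the volume onto a transducer-frame simulation lattice.

    Intensities are trilinearly interpolated; labels use nearest-neighbour.
    Lattice points outside the scan are air (intensity fill, label 0).
    """
    pts_ras = pose.to_ras(grid.points())
    vox = volume.ras_to_voxel(pts_ras).T
    intens = ndimage.map_coordinates(volume.intensities, vox, order=1,
                                     mode="constant", cval=AIR_FILL_VALUE
                                     ).reshape(grid.shape)
    labels = None
    if volume.labels is not None:
        labels = ndimage.map_coordinates(volume.labels, vox, order=0,
                                         mode="constant", cval=0
                                         ).reshape(grid.shape)
    return intens, labels


def sample_ray(volume: HeadVolume, p0, p1, step_mm: float = 0.5,
               fill: float = AIR_FILL_VALUE) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear intensity samples along the segment p0 -> p1 (RAS mm).

    Samples sit at p0 + k*step*unit for k = 0..floor(|p1-p0|/step). Returns
    (arc lengths mm, intensities). Coincident endpoints give one sample.
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0.0:
        return np.zeros(1), volume.sample(p0[None, :], fill=fill)
    n = int(np.floor(length / step_mm))
    arc = np.arange(n + 1) * step_mm
    pts = p0 + (arc / length)[:, None] * (p1 - p0)
    return arc, volume.sample(pts, fill=fill)
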