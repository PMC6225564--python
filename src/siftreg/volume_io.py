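"""Volumes with physical-space metadata, file I/O, and resampling.

The physical coordinate model follows the convention of the major
medical-imaging toolkits (ITK/NIfTI): a volume is a 3D scalar grid with
0-based voxel indices ``(i, j, k)``; the physical position (mm) of the
*center* of voxel ``(0, 0, 0)`` is the origin, and

    physical = origin + direction @ (spacing * index)

with ``direction`` a 3x3 orthonormal matrix whose columns are the physical
directions of the three index axes.  All distances elsewhere in this
package (RANSAC thresholds, match radii, landmark errors) are physical
millimetres, so this mapping is the contract every other module relies on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "resample_into",
]


class VolumeError(ValueError):
    """Raised for invalid volume metadata or dimensionality."""


def _as_float_array(x, shape, name):
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise VolumeError(f"{name} must have shape {shape}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise VolumeError(f"{name} must be finite")
    return a


@dataclass(frozen=True)
class Volume:
    """A 3D scalar intensity grid with physical-space metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units (CT values may be HU-like, CBCT
        values are typically uncalibrated).
    spacing : array-like of 3 floats
        Millimetres per voxel along each index axis; all > 0.
    origin : array-like of 3 floats
        Physical position (mm) of the center of voxel (0, 0, 0).
    direction : array-like, shape (3, 3)
        Orthonormal matrix; column ``a`` is the physical direction of
        index axis ``a``.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"volume data must be 3D, got {data.ndim}D")
        if min(data.shape) < 2:
            raise VolumeError(f"grid needs >= 2 voxels per axis, got {data.shape}")
        spacing = _as_float_array(self.spacing, (3,), "spacing")
        origin = _as_float_array(self.origin, (3,), "origin")
        direction = _as_float_array(self.direction, (3, 3), "direction")
        if np.any(spacing <= 0):
            raise VolumeError(f"spacing must be positive, got {spacing}")
        if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
            raise VolumeError("direction matrix must be orthonormal (tol 1e-6)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_physical(self, index) -> np.ndarray:
        """Map continuous voxel coordinates (..., 3) to physical mm points.

        Indices outside the grid are allowed; the map is affine.
        """
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def physical_to_voxel(self, point) -> np.ndarray:
        """Inverse of :meth:`voxel_to_physical` (exact, the map is affine)."""
        point = np.asarray(point, dtype=float)
        return ((point - self.origin) @ self.direction) / self.spacing

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid and metadata, new intensities."""
        return Volume(data, self.spacing, self.origin, self.direction)

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).astype(float)
        return self.voxel_to_physical(idx)


def _from_sitk(img: sitk.Image) -> Volume:
    if img.GetDimension() != 3:
        raise VolumeError(f"expected a 3D image, got {img.GetDimension()}D")
    # sitk arrays come back (z, y, x); transpose to (x, y, z) index order
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return Volume(data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()), direction)


def _to_sitk(volume: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.ravel()))
    return img


def read_volume(path: str | os.PathLike, format_hint: str | None = None) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) file, or a
    DICOM-series directory, into a :class:`Volume`.

    ``format_hint`` may be ``"dicom"`` to force series reading on a
    directory; otherwise the format is inferred from the path.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file or directory: {path}")
    is_dir = os.path.isdir(path)
    try:
        if is_dir or format_hint == "dicom":
            reader = sitk.ImageSeriesReader()
            files = reader.GetGDCMSeriesFileNames(path)
            if not files:
                raise IOError(f"no DICOM series found in {path}")
            reader.SetFileNames(files)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(path)
    except VolumeError:
        raise
    except RuntimeError as exc:
        raise IOError(f"could not read image {path}: {exc}") from exc
    return _from_sitk(img)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI or MetaImage; metadata round-trips losslessly
    (within file-format float precision)."""
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    try:
        sitk.WriteImage(_to_sitk(volume), path)
    except RuntimeError as exc:
        raise IOError(f"could not write image {path}: {exc}") from exc


def resample_into(
    source: Volume,
    transform,
    reference: Volume,
    interpolation: str = "linear",
    fill_value: float = 0.0,
) -> Volume:
    """Resample ``source`` onto ``reference``'s grid through ``transform``.

    ``transform`` maps *reference* physical points to *source* physical
    points (a callable on (N, 3) arrays, an object with a
    ``transform_points`` method, or ``None`` for identity).  Each output
    voxel holds the source intensity interpolated at the mapped point;
    points mapping outside the source grid receive ``fill_value``.
    """
    from scipy.ndimage import map_coordinates

    pts = reference.grid_points().reshape(-1, 3)
    if transform is None:
        mapped = pts
    elif hasattr(transform, "transform_points"):
        mapped = transform.transform_points(pts)
    else:
        mapped = transform(pts)
    coords = source.physical_to_voxel(mapped).T  # (3, N)
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = map_coordinates(
        source.data.astype(float), coords, order=order, mode="constant", cval=fill_value
    )
    return reference.with_data(out.reshape(reference.shape))
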