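"""NIfTI-backed containers for CT volumes and binary masks.

All downstream geometry is carried out in physical millimeters, so the two
containers defined here pin down the spatial bookkeeping once:

* index order is ``(slice, row, col)`` = ``(z, y, x)``; "top of the heart"
  means the highest slice index;
* coordinates are voxel-center based and 0-indexed: the physical position of
  voxel ``(i, j, k)`` is ``origin + index * spacing``;
* ``spacing`` is ``(dz, dy, dx)`` in mm, typically anisotropic for calcium
  score CT (e.g. 2.5 mm slices, 0.5 mm in-plane pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "BinaryMask", "read_volume", "read_mask", "write_volume"]


def _validate_geometry(data: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if any(n < 2 for n in data.shape):
        raise ValueError(f"grid too small: shape={data.shape}, need >= (2,2,2)")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
    if len(origin) != 3:
        raise ValueError(f"origin must have 3 components, got {origin}")
    return spacing, origin


@dataclass
class ImageVolume:
    """A 3D HU grid with physical spacing and origin.

    Attributes
    ----------
    data : ndarray, shape (n_slices, n_rows, n_cols)
        Hounsfield units, axis order (z, y, x).
    spacing : tuple of float
        Voxel spacing (dz, dy, dx) in mm; strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _validate_geometry(self.data, self.spacing, self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class BinaryMask:
    """A 3D boolean grid sharing the :class:`ImageVolume` geometry convention."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.spacing, self.origin = _validate_geometry(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def indices_mm(self) -> np.ndarray:
        """Physical (z, y, x) mm coordinates of foreground voxels, shape (n, 3)."""
        idx = np.argwhere(self.data).astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    # Data axes are (z, y, x); nibabel's affine maps array axes to world
    # (x, y, z), so the diagonal is reversed relative to our spacing order.
    aff = np.eye(4)
    aff[0, 0] = spacing[2]
    aff[1, 1] = spacing[1]
    aff[2, 2] = spacing[0]
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def _geometry_from_img(img) -> tuple[tuple, tuple]:
    zooms = img.header.get_zooms()[:3]
    # nibabel axis order (x, y, z) -> ours (z, y, x)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    origin = (float(t[2]), float(t[1]), float(t[0]))
    return spacing, origin


def read_volume(path) -> ImageVolume:
    """Read a NIfTI file into an :class:`ImageVolume`.

    HU values of integer-typed files are preserved bit-exactly; voxel spacing
    is taken from the header zooms.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    arr = np.asanyarray(img.dataobj)
    # stored axis order (x, y, z) -> (z, y, x)
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    spacing, origin = _geometry_from_img(img)
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def read_mask(path) -> BinaryMask:
    """Read a NIfTI file as a :class:`BinaryMask` (nonzero voxels = foreground)."""
    vol = read_volume(path)
    return BinaryMask(data=vol.data != 0, spacing=vol.spacing, origin=vol.origin)


def write_volume(vol, path) -> None:
    """Write an :class:`ImageVolume` or :class:`BinaryMask` as NIfTI-1.

    Masks are written as 8-bit integers in {0, 1}; float volumes as float32,
    integer volumes with their integer dtype.
    """
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data
        if not np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float32)
    arr = np.transpose(data, (2, 1, 0))  # back to nibabel (x, y, z)
    img = nib.Nifti1Image(arr, _affine_from_geometry(vol.spacing, vol.origin))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))
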