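"""EAT mask derivation and spatial subdivision of the pericardial sac.

Given a pericardial-sac segmentation, epicardial adipose tissue (EAT) is the
sac tissue whose attenuation falls in the CT fat window (default
[-190, -30] HU, the conventional adipose range), computed on a noise-reduced
volume (per-slice 3x3 median filter).

Two spatial subdivisions localize where fat sits:

* **axial slabs** PQ1..PQ4 — the occupied slice range of the sac split into
  four near-equal consecutive blocks, PQ1 at the bottom of the heart and PQ4
  at the top (where most pericoronary fat lives);
* **radial shells** Shell1..Shell4 — concentric ribbons from the sac surface
  inward, obtained by eroding the sac by multiples of w = L/8 where L is the
  sac's major principal axis length; erosion is a physical-distance
  criterion (mm-scaled distance transform) so anisotropic 2.5 mm slices are
  honored.

Both subdivisions exactly partition their parent mask voxelwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, ImageVolume

__all__ = [
    "FatWindow",
    "SubregionSet",
    "median_filter_slices",
    "eat_mask_from_sac",
    "axial_slabs",
    "radial_shells",
]

SLAB_LABELS = ("PQ1", "PQ2", "PQ3", "PQ4")
SHELL_LABELS = ("Shell1", "Shell2", "Shell3", "Shell4")


@dataclass(frozen=True)
class FatWindow:
    """Inclusive HU window defining adipose tissue on CT."""

    lo: float = -190.0
    hi: float = -30.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"fat window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, hu: np.ndarray) -> np.ndarray:
        return (hu >= self.lo) & (hu <= self.hi)


@dataclass
class SubregionSet:
    """A labeled, pairwise-disjoint partition of a parent mask."""

    labels: list
    masks: list
    parent: str = "sac"

    def __post_init__(self):
        if len(self.labels) != len(self.masks):
            raise ValueError("labels and masks must align")

    def __iter__(self):
        return iter(zip(self.labels, self.masks))

    def __getitem__(self, label):
        return self.masks[self.labels.index(label)]

    def verify_partition(self, parent: BinaryMask) -> None:
        """Assert disjointness and exact voxelwise union with the parent."""
        total = np.zeros(parent.shape, dtype=np.int64)
        for m in self.masks:
            total += m.data
        if total.max() > 1:
            raise AssertionError(f"{self.parent} subregions overlap")
        if not np.array_equal(total.astype(bool), parent.data):
            raise AssertionError(f"{self.parent} subregions do not cover the parent")

    def label_map(self) -> np.ndarray:
        """Integer label volume: 0 background, 1..n subregions."""
        out = np.zeros(self.masks[0].shape, dtype=np.uint8)
        for i, m in enumerate(self.masks, start=1):
            out[m.data] = i
        return out


def median_filter_slices(vol: ImageVolume) -> ImageVolume:
    """Apply a 2D 3x3 median filter independently to every axial slice."""
    filtered = ndimage.median_filter(vol.data, size=(1, 3, 3), mode="nearest")
    return ImageVolume(data=filtered, spacing=vol.spacing, origin=vol.origin)


def eat_mask_from_sac(
    vol: ImageVolume,
    sac: BinaryMask,
    window: FatWindow = FatWindow(),
    prefiltered: bool = False,
) -> BinaryMask:
    """Fat voxels inside the pericardial sac.

    The volume is median-filtered slice-wise first (skip with
    ``prefiltered=True`` if the caller already did), then thresholded to the
    fat window and intersected with the sac mask.
    """
    if not vol.same_geometry(sac):
        raise ValueError(
            f"volume/sac geometry mismatch: {vol.shape}/{vol.spacing} vs {sac.shape}/{sac.spacing}"
        )
    work = vol if prefiltered else median_filter_slices(vol)
    data = sac.data & window.contains(work.data)
    if not data.any():
        warnings.warn("EAT mask is empty for this sac", stacklevel=2)
    return BinaryMask(data=data, spacing=vol.spacing, origin=vol.origin)


def axial_slabs(parent: BinaryMask) -> SubregionSet:
    """Split the occupied slice range into 4 consecutive blocks PQ1..PQ4.

    PQ1 is the bottom of the heart (lowest occupied slice index), PQ4 the
    top. Remainder slices go to the bottom-most slabs first, so block sizes
    differ by at most one.
    """
    occupied = np.flatnonzero(parent.data.any(axis=(1, 2)))
    if occupied.size == 0:
        raise ValueError("parent mask is empty")
    lo, hi = int(occupied[0]), int(occupied[-1])
    n = hi - lo + 1
    if n < 4:
        raise ValueError(f"need >= 4 occupied slices for axial slabs, got {n}")
    base, rem = divmod(n, 4)
    sizes = [base + 1] * rem + [base] * (4 - rem)  # bottom-first remainder
    masks, start = [], lo
    for size in sizes:
        block = np.zeros(parent.shape, dtype=bool)
        block[start : start + size] = parent.data[start : start + size]
        masks.append(BinaryMask(block, parent.spacing, parent.origin))
        start += size
    return SubregionSet(labels=list(SLAB_LABELS), masks=masks, parent="sac")


def _erode_mm(mask: BinaryMask, radius_mm: float, edt: np.ndarray | None = None) -> np.ndarray:
    """Erode a mask by a physical radius via distance-transform thresholding."""
    if edt is None:
        edt = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    return edt > radius_mm


def radial_shells(sac: BinaryMask, major_axis_len: float) -> SubregionSet:
    """Four concentric ribbons of the sac, outermost (Shell1) to core (Shell4).

    Shell widths are w = major_axis_len / 8 so that three erosions of width
    w, 2w, 3w peel successive boundary layers and Shell4 keeps whatever core
    remains. Erosion uses the anisotropy-aware Euclidean distance transform,
    so widths are true millimeters regardless of voxel shape.
    """
    if sac.n_voxels == 0:
        raise ValueError("sac mask is empty")
    if major_axis_len <= 0:
        raise ValueError(f"major_axis_len must be > 0, got {major_axis_len}")
    w = major_axis_len / 8.0
    edt = ndimage.distance_transform_edt(sac.data, sampling=sac.spacing)
    eroded = [sac.data] + [_erode_mm(sac, i * w, edt=edt) for i in (1, 2, 3)]
    masks = []
    for i in range(3):
        masks.append(BinaryMask(eroded[i] & ~eroded[i + 1], sac.spacing, sac.origin))
    masks.append(BinaryMask(eroded[3], sac.spacing, sac.origin))
    if masks[-1].n_voxels == 0:
        warnings.warn("innermost shell (Shell4) is empty after erosion", stacklevel=2)
    return SubregionSet(labels=list(SHELL_LABELS), masks=masks, parent="sac")
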