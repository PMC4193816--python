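"""CT volume container and NIfTI-1 I/O.

A :class:`CTVolume` is an axis-aligned scalar field of Hounsfield units.
Array index order is ``(i, j, k)`` with ``k`` the axial (inferior->superior)
axis, so axial slices are constant-``k`` planes.  World coordinates are in
millimetres, ``world = origin + index * spacing``; no rotation or shear is
supported (non-contrast cardiac acquisitions are reconstructed axially).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "read_volume", "write_volume", "VolumeFormatError"]


class VolumeFormatError(ValueError):
    """Raised for volumes this package cannot represent (oblique affines, bad headers)."""


@dataclass
class CTVolume:
    """Hounsfield-unit grid with voxel spacing and world origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError("CT volume must be 3-D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise VolumeFormatError("spacing must be three positive values (mm)")
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm to fractional voxel indices."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def axial_slice(self, k: int) -> np.ndarray:
        """The axial plane at index ``k`` (shape ``(ni, nj)``)."""
        return self.data[:, :, k]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def contains_world(self, xyz: np.ndarray) -> bool:
        v = self.world_to_voxel(xyz)
        return bool(np.all(v >= 0) and np.all(v <= np.array(self.shape) - 1))


def _affine(volume: CTVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(volume.spacing)
    aff[:3, 3] = volume.origin
    return aff


def write_volume(volume: CTVolume, path: str) -> None:
    """Write as NIfTI-1 with HU stored as signed 16-bit integers."""
    data = np.rint(volume.data).astype(np.int16)
    img = nib.Nifti1Image(data, _affine(volume))
    img.header.set_data_dtype(np.int16)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, path)


def read_volume(path: str) -> CTVolume:
    """Read a NIfTI-1 volume; only axis-aligned (diagonal-affine) images are accepted."""
    try:
        img = nib.load(path)
        aff = img.affine
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header / truncated file
        raise VolumeFormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if aff is None:
        raise VolumeFormatError(f"{path!r} has no affine / spacing metadata")
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise VolumeFormatError(
            f"{path!r}: oblique or rotated orientation is unsupported (affine must be diagonal)"
        )
    spacing = np.diag(rot).copy()
    origin = aff[:3, 3].copy()
    if np.any(spacing < 0):
        # normalise flipped axes to a positive-spacing, origin-shifted representation
        for ax in np.where(spacing < 0)[0]:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
            spacing[ax] = -spacing[ax]
    if np.any(spacing == 0):
        raise VolumeFormatError(f"{path!r}: zero voxel spacing in header")
    return CTVolume(np.asarray(data, dtype=np.float32), spacing, origin)
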