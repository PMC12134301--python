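"""Volumetric containers and NIfTI I/O.

Coordinate convention used throughout the package: patient x = lateral,
y = superior-inferior (SI), z = anterior-posterior (AP).  A volume's
``values[i, j, k]`` voxel centre sits at ``origin + spacing * (i, j, k)``
in mm, with the treatment isocentre at the coordinate origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume", "BinaryVolume", "read_volume", "write_volume"]


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical spacing and isocentre-relative origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Linear attenuation in consistent units of mm^-1.
    spacing : ndarray, shape (3,)
        Voxel pitch in mm per axis; strictly positive.
    origin : ndarray, shape (3,)
        mm offset of the centre of voxel (0, 0, 0) from the isocentre.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=np.float64), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.origin is None:
            # centre the grid on the isocentre by default
            self.origin = -self.spacing * (np.array(self.values.shape) - 1) / 2.0
        self.origin = np.broadcast_to(np.asarray(self.origin, dtype=np.float64), (3,)).copy()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) mm corners of the grid's bounding box (voxel edges)."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-centre coordinates in mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )  # type: ignore[return-value]

    def same_grid(self, other: "VoxelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.values.copy(), self.spacing.copy(), self.origin.copy())

    def crop_to_support(self, margin: int = 1) -> "VoxelVolume":
        """Crop to the bounding box of nonzero voxels (plus ``margin``).

        The origin is adjusted so world coordinates are preserved; line
        integrals through the cropped volume equal those through the
        original, since only zero attenuation is removed.  An all-zero
        volume is returned unchanged.
        """
        nz = np.nonzero(self.values)
        if len(nz[0]) == 0:
            return self.copy()
        sl = []
        for ax in range(3):
            lo = max(int(nz[ax].min()) - margin, 0)
            hi = min(int(nz[ax].max()) + margin + 1, self.shape[ax])
            sl.append(slice(lo, hi))
        vals = self.values[tuple(sl)].copy()
        origin = self.origin + self.spacing * np.array([s.start for s in sl])
        return VoxelVolume(vals, self.spacing.copy(), origin)


class BinaryVolume(VoxelVolume):
    """A VoxelVolume whose values are constrained to {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        bad = ~np.isin(self.values, (0.0, 1.0))
        if np.any(bad):
            raise ValueError("binary volume must contain only 0/1 values")

    @property
    def mask(self) -> np.ndarray:
        return self.values.astype(bool)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, preserving spacing and origin in the header."""
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path, binary: bool = False) -> VoxelVolume:
    """Read a NIfTI volume written by :func:`write_volume`.

    Raises
    ------
    ValueError
        If the file does not contain a 3D image.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got shape {data.shape}")
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    cls = BinaryVolume if binary else VoxelVolume
    return cls(data, spacing, origin)
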