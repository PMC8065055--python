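"""Regular 3-D voxel grids: images and binary label masks.

Arrays are stored in ITK index order ``(i, j, k)`` (fastest axis first in
physical x), and the physical position of voxel ``(i, j, k)`` is
``origin + direction @ (spacing * (i, j, k))`` in millimetres, LPS.
Conversion to and from SimpleITK (whose numpy views are reversed, z-first)
is handled here so the rest of the package never worries about axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = ["GridMismatchError", "VolumeImage", "LabelMask"]


class GridMismatchError(ValueError):
    """Two volumes expected on the same voxel grid are not."""


def _validate_grid(spacing, origin, direction):
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    direction = np.asarray(direction, dtype=float).reshape(3, 3)
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be positive, got {spacing}")
    if np.max(np.abs(direction.T @ direction - np.eye(3))) > 1e-6:
        raise ValueError("direction matrix must be orthonormal within 1e-6")
    return spacing, origin, direction


@dataclass
class _Grid:
    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame: str = "world"

    def __post_init__(self):
        self.spacing, self.origin, self.direction = _validate_grid(
            self.spacing, self.origin, self.direction
        )
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"voxels must be a 3-D array, got ndim={v.ndim}")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """(…, 3) voxel indices -> (…, 3) physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    def physical_grid(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1)
        return self.index_to_physical(idx)

    def same_grid(self, other: "_Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def require_same_grid(self, other: "_Grid", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(f"{what} are not on the same voxel grid")

    # -- SimpleITK bridge ---------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        arr = np.ascontiguousarray(np.transpose(self.voxels, (2, 1, 0)))
        img = sitk.GetImageFromArray(arr.astype(np.float64, copy=False))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, frame: str = "world"):
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return cls(
            voxels=arr,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
            frame=frame,
        )

    def with_voxels(self, voxels: np.ndarray):
        return replace(self, voxels=voxels)


@dataclass
class VolumeImage(_Grid):
    """A scalar 3-D image on a regular grid with physical metadata."""

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(float, copy=False)


@dataclass
class LabelMask(_Grid):
    """A binary mask on the same grid model as :class:`VolumeImage`."""

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(bool, copy=False)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid of the mask's voxel centers."""
        if self.n_voxels == 0:
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.voxels)
        return self.index_to_physical(idx).mean(axis=0)

    def to_sitk(self) -> sitk.Image:
        arr = np.ascontiguousarray(np.transpose(self.voxels, (2, 1, 0)))
        img = sitk.GetImageFromArray(arr.astype(np.uint8))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img
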