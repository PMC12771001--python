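"""Volume, mask and displacement-field containers with NIfTI I/O.

One internal convention everywhere:

* array axes are ``(x, y, z)``, x fastest-varying in memory order terms of
  indexing ``data[i, j, k]``;
* voxel indices are 0-based; the world coordinate (mm) of voxel ``i`` is
  ``origin + i * spacing`` (voxel centers);
* displacement vectors are stored in mm along the world axes, never in voxel
  units, so anisotropic spacing is handled uniformly.

Only axis-aligned geometries are supported: a NIfTI whose rotation part is
not the identity (up to spacing scaling) is rejected with a clear error.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "LabelMask",
    "DisplacementField",
    "read_volume",
    "read_mask",
    "write_volume",
    "read_dvf",
    "write_dvf",
]


@dataclasses.dataclass
class VolumeGrid:
    """A 3D scalar grid (image intensities or dose in Gy) with geometry.

    Parameters
    ----------
    data:
        3D array of scalars.
    spacing:
        Voxel size in mm per axis, strictly positive.
    origin:
        World-mm coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World-mm coordinates of (possibly fractional) voxel indices."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world-mm coordinates."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def same_grid_as(self, other: "VolumeGrid | LabelMask | DisplacementField") -> bool:
        return (
            self.shape == tuple(other.data.shape[:3])
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other, what: str = "input") -> None:
        if not self.same_grid_as(other):
            raise ValueError(
                f"{what} grid mismatch: shape/spacing/origin "
                f"{other.data.shape[:3]}/{other.spacing}/{other.origin} vs "
                f"{self.shape}/{self.spacing}/{self.origin}"
            )


@dataclasses.dataclass
class LabelMask(VolumeGrid):
    """Binary organ mask on a :class:`VolumeGrid` geometry; values in {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def num_foreground(self) -> int:
        return int(self.data.sum())


@dataclasses.dataclass
class DisplacementField(VolumeGrid):
    """Per-voxel 3-vector of mm displacements in world axes (forward map).

    ``data`` has shape ``(nx, ny, nz, 3)``; the vector at voxel ``i`` is the
    displacement of the material point whose undeformed position is the voxel
    center, i.e. ``phi(x) = x + u(x)``.
    """

    phase_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError(
                f"displacement field must have shape (nx, ny, nz, 3), got {self.data.shape}"
            )
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)


# --------------------------------------------------------------------------
# NIfTI I/O


def _check_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    """Extract (spacing, origin), rejecting non-identity direction cosines."""
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: degenerate affine (zero spacing)")
    cosines = rot / spacing
    if not np.allclose(cosines, np.eye(3), atol=1e-3):
        raise ValueError(
            f"{path}: only identity direction cosines are supported, got\n{cosines}"
        )
    return spacing, affine[:3, 3].copy()


def _load(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    spacing, origin = _check_affine(img.affine, path)
    data = np.asarray(img.dataobj)
    return data, spacing, origin


def read_volume(path) -> VolumeGrid:
    """Read a 3D scalar NIfTI volume (image, dose map, ...)."""
    data, spacing, origin = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D volume, got {data.ndim}D")
    data = data.astype(float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return VolumeGrid(data=data, spacing=spacing, origin=origin)


def read_mask(path) -> LabelMask:
    """Read a binary 3D NIfTI mask; any nonzero voxel counts as foreground."""
    data, spacing, origin = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D mask, got {data.ndim}D")
    return LabelMask(data=(data > 0).astype(np.uint8), spacing=spacing, origin=origin)


def _affine(grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def write_volume(grid: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), _affine(grid))
    nib.save(img, str(path))


def write_mask(mask: LabelMask, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask.data, dtype=np.uint8), _affine(mask))
    nib.save(img, str(path))


def write_dvf(field: DisplacementField, path) -> None:
    """Write a displacement field as a 4D NIfTI with 3 components (mm)."""
    if not np.all(np.isfinite(field.data)):
        raise ValueError("refusing to write non-finite displacement field")
    img = nib.Nifti1Image(np.asarray(field.data, dtype=np.float32), _affine(field))
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_dvf(path, phase_index: int = 0) -> DisplacementField:
    data, spacing, origin = _load(path)
    if data.ndim == 5 and data.shape[3] == 1:  # tolerate the 5D vector layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"{path}: expected a (nx, ny, nz, 3) vector NIfTI, got {data.shape}")
    return DisplacementField(
        data=data.astype(float), spacing=spacing, origin=origin, phase_index=phase_index
    )
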