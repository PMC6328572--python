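"""Volumetric grid data model and NIfTI/DICOM I/O.

All modules share one coordinate convention, fixed here:

* voxel indices are 0-based and ordered ``(i, j, k)``, matching
  ``data[i, j, k]``;
* axis ``i`` maps to physical axis ``x``, ``j`` to ``y``, ``k`` to ``z``;
* a voxel's physical coordinate is its *center*:
  ``physical = origin + index * spacing`` (mm);
* every geometric quantity handed between modules (dilation radii,
  centerline points, mesh vertices, seeds) is expressed in mm.

No other module converts between index and physical space ad hoc; they go
through :meth:`Grid.index_to_physical` / :meth:`Grid.physical_to_index`.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np


class SeedLabel(str, enum.Enum):
    RCA_OSTIUM = "RCA_ostium"
    LM_OSTIUM = "LM_ostium"
    GENERIC = "generic"


@dataclass(frozen=True)
class Grid:
    """Lattice geometry: per-axis spacing and the physical position of voxel
    (0,0,0), both in mm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 2 for s in self.shape):
            raise ValueError(f"grid must be 3D with each axis >= 2, got shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, index) -> np.ndarray:
        """Map (continuous) voxel indices to mm coordinates."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, point) -> tuple[np.ndarray, np.ndarray]:
        """Map mm coordinates to continuous voxel indices.

        Returns ``(index, inside)`` where ``inside`` flags points whose
        continuous index lies within the lattice (points are never clamped).
        """
        idx = (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)
        upper = np.asarray(self.shape, dtype=float) - 1.0
        inside = np.all((idx >= -0.5) & (idx <= upper + 0.5), axis=-1)
        return idx, inside

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) corner mm coordinates of the voxel-center bounding box."""
        low = np.asarray(self.origin, dtype=float)
        high = low + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return low, high


@dataclass
class Volume:
    """3D scalar image on a :class:`Grid` (HU for CTA input, unitless for
    derived images such as vesselness or speed maps)."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    @classmethod
    def from_array(cls, data, spacing, origin=(0.0, 0.0, 0.0)) -> "Volume":
        data = np.asarray(data)
        return cls(data, Grid(tuple(data.shape), tuple(float(s) for s in spacing),
                              tuple(float(o) for o in origin)))

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    def with_data(self, data) -> "Volume":
        return Volume(np.asarray(data), self.grid)


@dataclass
class BinaryMask:
    """Boolean lattice sharing the grid of the Volume it annotates."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    @classmethod
    def from_array(cls, data, spacing, origin=(0.0, 0.0, 0.0)) -> "BinaryMask":
        data = np.asarray(data)
        return cls(data, Grid(tuple(data.shape), tuple(float(s) for s in spacing),
                              tuple(float(o) for o in origin)))

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume


@dataclass(frozen=True)
class SeedPoint:
    """User-provided seed at a coronary ostium, in mm."""

    position: tuple[float, float, float]
    label: SeedLabel = SeedLabel.GENERIC

    def validate_in(self, grid: Grid) -> None:
        _, inside = grid.physical_to_index(self.position)
        if not bool(inside):
            raise ValueError(f"seed {self.label.value} at {self.position} mm lies outside the volume bounds")


def _affine_from_grid(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(affine: np.ndarray, shape) -> tuple[Grid, np.ndarray]:
    """Decompose an affine into our canonical grid plus residual direction.

    The volume array is reordered/flipped so voxel axes align with +x,+y,+z;
    the original direction matrix is returned for provenance.
    """
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    direction = rot / spacing
    # permutation: physical axis dominated by each voxel axis
    perm = np.argmax(np.abs(direction), axis=0)
    if len(set(perm.tolist())) != 3:
        raise ValueError("affine direction matrix is too oblique to canonicalize")
    return spacing, direction, perm


def read_volume(path, format_hint: str | None = None) -> Volume:
    """Read a NIfTI file or a single-series DICOM directory as a Volume in HU.

    DICOM rescale slope/intercept is applied; the volume is reordered to the
    canonical axis convention (voxel axis i->x, j->y, k->z, positive
    direction). The original orientation matrix is kept in
    ``volume.direction`` metadata via attribute assignment.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file or directory: {path}")
    if os.path.isdir(path) or format_hint == "dicom":
        return _read_dicom_series(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    spacing, direction, perm = _grid_from_affine(affine, data.shape)
    # reorder voxel axes so axis i drives physical x, etc.
    inv = np.argsort(perm)
    data = np.transpose(data, inv)
    spacing = spacing[inv]
    signs = np.array([direction[perm[inv[a]], inv[a]] for a in range(3)])
    origin = affine[:3, 3].astype(float).copy()
    for a in range(3):
        if signs[a] < 0:
            data = np.flip(data, axis=a)
            origin[a] = origin[a] + signs[a] * spacing[a] * (data.shape[a] - 1)
    vol = Volume.from_array(np.ascontiguousarray(data), spacing, origin)
    vol.direction = direction  # provenance only
    return vol


def _read_dicom_series(directory: str) -> Volume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(directory)
    if not series_ids:
        raise IOError(f"no DICOM series found in {directory}")
    if len(series_ids) > 1:
        raise IOError(
            f"directory {directory} holds {len(series_ids)} DICOM series "
            f"({', '.join(series_ids)}); pass a directory with exactly one"
        )
    reader.SetFileNames(reader.GetGDCMSeriesFileNames(directory, series_ids[0]))
    img = reader.Execute()  # rescale slope/intercept applied by GDCM
    return from_sitk(img)


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as NIfTI; round-trips bit-exactly through read_volume."""
    img = nib.Nifti1Image(np.asarray(volume.data), _affine_from_grid(volume.grid))
    nib.save(img, os.fspath(path))


def write_mask(mask: BinaryMask, path) -> None:
    """Write a BinaryMask as a uint8 NIfTI."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine_from_grid(mask.grid))
    nib.save(img, os.fspath(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0, vol.grid)


# ---------------------------------------------------------------------------
# SimpleITK bridge. sitk orders axes (x, y, z) while GetArrayFromImage yields
# [z, y, x]; our arrays are [i=x, j=y, k=z], so the bridge transposes.

def to_sitk(volume: Volume | BinaryMask):
    import SimpleITK as sitk

    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in volume.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.grid.origin))
    return img


def from_sitk(img) -> Volume:
    import SimpleITK as sitk

    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    return Volume.from_array(data, img.GetSpacing(), img.GetOrigin())
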