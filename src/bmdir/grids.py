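"""Volumetric containers and grid operations.

Conventions used throughout the package:

* arrays are indexed ``(i, j, k)`` for the ``(x, y, z)`` axes;
* voxel centers sit at ``origin + index * spacing`` (0-based, mm);
* displacement fields follow the pull-back convention: the vector stored
  at fixed-space point ``x`` points to the corresponding moving-space
  point ``x + u(x)``, so warping resamples the *moving* image there.

All physical quantities are millimetres internally; converters to/from cm
exist only at I/O boundaries where a caller requests them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "DisplacementField",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "resample",
    "sample_dvf",
    "warp_image",
    "warp_mask",
]

_GRID_ATOL_MM = 1e-6


@dataclasses.dataclass
class ImageVolume:
    """A 3-D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    voxels
        Scalar array of shape ``(nx, ny, nz)``.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm, all positive.
    origin
        Physical coordinate (mm) of voxel ``(0, 0, 0)`` (voxel center).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.voxels.ndim}")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical mm coordinates of (fractional) voxel indices, shape (..., 3)."""
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical mm points, shape (..., 3)."""
        return (np.asarray(pts, dtype=float) - np.array(self.origin)) / np.array(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center coordinates, shape (nx, ny, nz, 3), mm."""
        nx, ny, nz = self.shape
        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                   indexing="ij"), axis=-1)
        return self.index_to_physical(idx)

    def grid_matches(self, other: "ImageVolume", atol: float = _GRID_ATOL_MM) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    def same_grid(self, voxels: np.ndarray) -> "ImageVolume":
        """A new volume with these voxels on this grid."""
        return type(self)(voxels, self.spacing, self.origin)


@dataclasses.dataclass
class BinaryMask(ImageVolume):
    """A 0/1 structure mask sharing the grid conventions of :class:`ImageVolume`."""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask voxels must be 0/1, found values {vals[:10]}")
        self.voxels = self.voxels.astype(np.uint8)
        super().__post_init__()

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        """Voxel-counted volume in mm^3."""
        return self.count * self.voxel_volume

    def same_grid(self, voxels: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(voxels) > 0.5, self.spacing, self.origin)


@dataclasses.dataclass
class DisplacementField(ImageVolume):
    """A 3-vector-per-voxel displacement field (mm) on the reference grid.

    Pull-back convention: ``u`` at fixed-space point ``x`` gives the
    corresponding moving-space location ``x + u(x)``.
    """

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4 or self.voxels.shape[-1] != 3:
            raise ValueError(
                f"displacement field must have shape (nx,ny,nz,3), got {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 2 for n in self.voxels.shape[:3]):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.voxels.shape}")

    @property
    def vectors(self) -> np.ndarray:
        return self.voxels

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.voxels, axis=-1)

    def same_grid(self, voxels: np.ndarray) -> "DisplacementField":
        return DisplacementField(voxels, self.spacing, self.origin)


@dataclasses.dataclass
class LandmarkSet:
    """Paired fixed/moving landmark coordinates in physical mm."""

    fixed: np.ndarray    # (n, 3)
    moving: np.ndarray   # (n, 3)
    labels: list[str] | None = None

    def __post_init__(self):
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.fixed.shape != self.moving.shape or self.fixed.shape[1] != 3:
            raise ValueError("fixed/moving must both be (n, 3)")
        if len(self.fixed) < 1:
            raise ValueError("need at least one landmark pair")
        if self.labels is None:
            self.labels = [f"lm{i}" for i in range(len(self.fixed))]
        if len(self.labels) != len(self.fixed):
            raise ValueError("one label per landmark pair required")

    def __len__(self) -> int:
        return len(self.fixed)


# ---------------------------------------------------------------------------
# I/O (SimpleITK backend: NIfTI-1 scalar/vector, NRRD scalar)
# ---------------------------------------------------------------------------

def _normalize_direction(img: sitk.Image) -> sitk.Image:
    """Reorient an image whose direction matrix is a signed permutation to identity.

    Oblique (non-axis-aligned) orientations are rejected.
    """
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    if np.allclose(d, np.eye(3), atol=1e-9):
        return img
    rounded = np.round(d)
    if not np.allclose(d, rounded, atol=1e-6) or not np.allclose(
            np.abs(rounded) @ np.ones(3), np.ones(3)):
        raise ValueError("oblique direction matrices are not supported")
    flip = sitk.DICOMOrientImageFilter()
    flip.SetDesiredCoordinateOrientation("LPS")  # identity direction in ITK space
    return flip.Execute(img)


def read_volume(path: str | Path, kind: str = "image"):
    """Read a NIfTI/NRRD volume as an image, mask, or displacement field.

    ``kind='dvf'`` expects a 3-component vector image (or 4-D NIfTI with the
    last dimension of length 3); vectors are returned in mm in physical space.
    ``kind='mask'`` enforces voxels in {0, 1}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() == 4:  # 4-D NIfTI DVF: fold last axis into components
        arr4 = sitk.GetArrayFromImage(img)  # (t, z, y, x)
        if arr4.shape[0] != 3:
            raise ValueError(f"4-D volume must carry 3 components, got {arr4.shape[0]}")
        vec = np.stack([arr4[c].transpose(2, 1, 0) for c in range(3)], axis=-1)
        spacing = img.GetSpacing()[:3]
        origin = img.GetOrigin()[:3]
        return DisplacementField(vec, spacing, origin)
    img = _normalize_direction(img)
    spacing = img.GetSpacing()
    origin = img.GetOrigin()
    arr = sitk.GetArrayFromImage(img)
    if kind == "dvf":
        if img.GetNumberOfComponentsPerPixel() != 3:
            raise ValueError("a DVF requires a 3-component vector image")
        vec = arr.transpose(2, 1, 0, 3)
        return DisplacementField(vec, spacing, origin)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(f"expected a scalar image for kind={kind!r}")
    arr = arr.transpose(2, 1, 0)
    if kind == "mask":
        return BinaryMask(arr, spacing, origin)
    if kind == "image":
        return ImageVolume(arr.astype(float), spacing, origin)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an image/mask/DVF to NIfTI or NRRD (chosen by file extension)."""
    if isinstance(vol, DisplacementField):
        img = sitk.GetImageFromArray(vol.voxels.transpose(2, 1, 0, 3), isVector=True)
    else:
        arr = vol.voxels
        if isinstance(vol, BinaryMask):
            arr = arr.astype(np.uint8)
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(Path(path)))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV with columns label,fx,fy,fz,mx,my,mz (mm)."""
    df = pd.read_csv(path)
    need = ["label", "fx", "fy", "fz", "mx", "my", "mz"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns {missing}")
    return LandmarkSet(df[["fx", "fy", "fz"]].to_numpy(),
                       df[["mx", "my", "mz"]].to_numpy(),
                       df["label"].astype(str).tolist())


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame({
        "label": lms.labels,
        "fx": lms.fixed[:, 0], "fy": lms.fixed[:, 1], "fz": lms.fixed[:, 2],
        "mx": lms.moving[:, 0], "my": lms.moving[:, 1], "mz": lms.moving[:, 2],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resampling / sampling / warping
# ---------------------------------------------------------------------------

def _sample_scalar(vol: ImageVolume, pts_mm: np.ndarray, *, mode: str,
                   cval: float = 0.0) -> np.ndarray:
    """Trilinear sample of a scalar volume at physical points (any shape + (3,))."""
    pts_mm = np.asarray(pts_mm, dtype=float)
    idx = vol.physical_to_index(pts_mm)
    coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
    out = ndimage.map_coordinates(vol.voxels.astype(float), coords, order=1,
                                  mode=mode, cval=cval)
    return out.reshape(pts_mm.shape[:-1])


def resample(vol: ImageVolume, new_spacing: Sequence[float]) -> ImageVolume:
    """Resample a volume to a new spacing with trilinear interpolation.

    The physical extent is preserved to within one voxel; masks are
    interpolated trilinearly then re-thresholded at 0.5.
    """
    new_spacing = tuple(float(s) for s in new_spacing)
    if any(s <= 0 for s in new_spacing):
        raise ValueError("new spacing must be positive")
    old_spacing = np.array(vol.spacing)
    new_shape = tuple(
        max(2, int(round((n - 1) * o / s)) + 1)
        for n, o, s in zip(vol.shape, old_spacing, new_spacing))
    if any(n < 2 for n in new_shape):
        raise ValueError("resampled grid degenerate (< 2 voxels along an axis)")
    if np.allclose(new_spacing, vol.spacing, atol=1e-12) and new_shape == vol.shape:
        return type(vol)(vol.voxels.copy(), vol.spacing, vol.origin)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij"),
                   axis=-1).astype(float)
    pts = idx * np.array(new_spacing) + np.array(vol.origin)
    if isinstance(vol, BinaryMask):
        frac = _sample_scalar(ImageVolume(vol.voxels.astype(float), vol.spacing,
                                          vol.origin), pts, mode="nearest")
        return BinaryMask(frac > 0.5, new_spacing, vol.origin)
    out = _sample_scalar(vol, pts, mode="nearest")
    return ImageVolume(out, new_spacing, vol.origin)


def sample_dvf(dvf: DisplacementField, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a DVF at physical points (n, 3) -> (n, 3) mm.

    Points outside the grid are clamped to the edge: surface-mesh nodes may
    sit exactly on (or a round-off beyond) the grid boundary.
    """
    if not np.all(np.isfinite(dvf.voxels)):
        raise ValueError("DVF contains non-finite values")
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    idx = dvf.physical_to_index(points_mm)  # (n, 3)
    coords = idx.T
    out = np.empty((len(points_mm), 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(dvf.voxels[..., c], coords, order=1,
                                            mode="nearest")
    return out


def warp_image(moving: ImageVolume, dvf: DisplacementField,
               fill_value: float = 0.0) -> ImageVolume:
    """Warp a moving image onto the reference grid of the DVF.

    Output value at fixed voxel center ``x`` is the trilinear sample of the
    moving image at ``x + u(x)``; samples outside the moving image get
    ``fill_value``.
    """
    pts = _reference_points(dvf)
    out = _sample_scalar(moving, pts, mode="constant", cval=fill_value)
    return ImageVolume(out, dvf.spacing, dvf.origin)


def warp_mask(structure: BinaryMask, dvf: DisplacementField) -> BinaryMask:
    """Warp a binary structure: trilinear warp of the 0/1 field, threshold 0.5."""
    pts = _reference_points(dvf)
    frac = _sample_scalar(ImageVolume(structure.voxels.astype(float),
                                      structure.spacing, structure.origin),
                          pts, mode="constant", cval=0.0)
    return BinaryMask(frac > 0.5, dvf.spacing, dvf.origin)


def _reference_points(dvf: DisplacementField) -> np.ndarray:
    """Mapped physical points x + u(x) for every voxel of the reference grid."""
    nx, ny, nz = dvf.shape
    idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                               indexing="ij"), axis=-1).astype(float)
    return idx * np.array(dvf.spacing) + np.array(dvf.origin) + dvf.voxels
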