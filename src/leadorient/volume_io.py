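"""NIfTI CT volume I/O, world-coordinate sampling and oblique-plane resampling.

All geometry is done in world (RAS+ millimetre) coordinates as encoded by the
NIfTI affine, so anisotropic and oblique acquisitions need no special casing.
Interpolation is trilinear throughout: it is exact on affine HU fields, which
makes the resampler analytically testable, and it is smooth enough for the
HU averaging the orientation detectors perform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, EmptySliceError, InvalidGeometryError

#: Hounsfield value of air, used as the default out-of-volume fill.
AIR_HU = -1024.0


@dataclass(frozen=True)
class CTVolume:
    """A 3D grid of Hounsfield-unit values with a voxel-to-world affine map.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values; finite floats.
    affine : ndarray, shape (4, 4)
        Maps homogeneous voxel indices to world millimetres (RAS+).
    """

    voxels: np.ndarray
    affine: np.ndarray
    _inv_affine: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float64)
        aff = np.asarray(self.affine, dtype=np.float64)
        if vox.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {vox.ndim} dimensions"
            )
        if aff.shape != (4, 4):
            raise InvalidGeometryError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise InvalidGeometryError("affine is singular")
        if not np.all(np.isfinite(vox)):
            raise InvalidGeometryError("volume contains non-finite HU values")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "_inv_affine", np.linalg.inv(aff))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Column norms of the affine's linear part: per-axis voxel size."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass(frozen=True)
class PlaneSpec:
    """An oblique plane through world space on which to resample HU values.

    ``basis_u``/``basis_v`` are orthonormal world unit vectors spanning the
    plane; ``extent_mm`` is (width along u, height along v).
    """

    center: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    extent_mm: tuple[float, float]
    resolution_mm: float = 0.1

    def __post_init__(self):
        c = np.asarray(self.center, dtype=np.float64)
        u = np.asarray(self.basis_u, dtype=np.float64)
        v = np.asarray(self.basis_v, dtype=np.float64)
        if abs(np.linalg.norm(u) - 1.0) > 1e-9 or abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise InvalidGeometryError("plane basis vectors must be unit length")
        if abs(float(u @ v)) > 1e-9:
            raise InvalidGeometryError("plane basis vectors must be orthogonal")
        if self.resolution_mm <= 0:
            raise InvalidGeometryError("resolution_mm must be positive")
        if self.extent_mm[0] <= 0 or self.extent_mm[1] <= 0:
            raise InvalidGeometryError("extent_mm components must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "basis_u", u)
        object.__setattr__(self, "basis_v", v)

    @property
    def grid_shape(self) -> tuple[int, int]:
        ni = int(round(self.extent_mm[0] / self.resolution_mm))
        nj = int(round(self.extent_mm[1] / self.resolution_mm))
        return ni, nj

    def pixel_to_world(self, i, j) -> np.ndarray:
        """Map (fractional) pixel indices to world points.

        ``p(i, j) = center + (i - ci)*res*basis_u + (j - cj)*res*basis_v``
        with (ci, cj) the pixel-grid center.
        """
        ni, nj = self.grid_shape
        ci, cj = (ni - 1) / 2.0, (nj - 1) / 2.0
        i = np.asarray(i, dtype=np.float64)
        j = np.asarray(j, dtype=np.float64)
        return (
            self.center
            + np.multiply.outer((i - ci) * self.resolution_mm, self.basis_u)
            + np.multiply.outer((j - cj) * self.resolution_mm, self.basis_v)
        )


@dataclass(frozen=True)
class Slice2D:
    """A resampled 2D HU slice together with the plane it was sampled on."""

    values: np.ndarray
    spec: PlaneSpec

    def pixel_to_world(self, i, j) -> np.ndarray:
        return self.spec.pixel_to_world(i, j)


def load_ct(path: str | Path) -> CTVolume:
    """Load a 3D NIfTI CT volume.

    The affine is taken from the file's sform if present, else the qform;
    a file with neither is rejected. Values are returned with the file's
    scl_slope/scl_inter applied (nibabel's default behaviour) and no further
    rescaling.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"expected a 3D CT volume, file has shape {img.shape}"
        )
    hdr = img.header
    sform_code = int(hdr["sform_code"]) if "sform_code" in hdr else 0
    qform_code = int(hdr["qform_code"]) if "qform_code" in hdr else 0
    if sform_code > 0:
        affine = img.get_sform()
    elif qform_code > 0:
        affine = img.get_qform()
    else:
        raise InvalidGeometryError(f"{path}: neither sform nor qform is set")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return CTVolume(voxels=data, affine=affine)


def save_nifti(volume: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as NIfTI-1, float32, with sform and qform set."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine)
    img.set_sform(volume.affine, code=1)
    img.set_qform(volume.affine, code=1)
    nib.save(img, str(path))


def world_to_voxel(ct: CTVolume, xyz) -> np.ndarray:
    """Map world points (mm) to continuous voxel indices (no clipping)."""
    xyz = np.asarray(xyz, dtype=np.float64)
    single = xyz.ndim == 1
    xyz = np.atleast_2d(xyz)
    out = xyz @ ct._inv_affine[:3, :3].T + ct._inv_affine[:3, 3]
    return out[0] if single else out


def voxel_to_world(ct: CTVolume, ijk) -> np.ndarray:
    """Map continuous voxel indices to world points (mm)."""
    ijk = np.asarray(ijk, dtype=np.float64)
    single = ijk.ndim == 1
    ijk = np.atleast_2d(ijk)
    out = ijk @ ct.affine[:3, :3].T + ct.affine[:3, 3]
    return out[0] if single and out.shape[0] == 1 else out


def sample_trilinear(ct: CTVolume, xyz, fill: float = AIR_HU) -> np.ndarray | float:
    """Trilinear HU interpolation at world points.

    Returns ``fill`` for any query whose 8-voxel neighbourhood is not fully
    inside the grid (i.e. any continuous index outside [0, n-1]); artifact
    sampling circles may graze the volume edge, and erroring there would be
    unhelpful.
    """
    pts = np.asarray(xyz, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    vox = pts @ ct._inv_affine[:3, :3].T + ct._inv_affine[:3, 3]
    vals = ndimage.map_coordinates(
        ct.voxels, vox.T, order=1, mode="constant", cval=fill
    )
    upper = np.array(ct.shape, dtype=np.float64) - 1.0
    outside = np.any((vox < 0.0) | (vox > upper), axis=1)
    vals = np.where(outside, fill, vals)
    return float(vals[0]) if single else vals


def resample_plane(ct: CTVolume, plane: PlaneSpec, fill: float = AIR_HU) -> Slice2D:
    """Resample the CT on an oblique plane.

    Each output pixel is the trilinear sample at its mapped world point.
    Raises :class:`EmptySliceError` when every pixel falls outside the volume.
    """
    ni, nj = plane.grid_shape
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    pts = plane.pixel_to_world(ii.ravel(), jj.ravel())
    vox = pts @ ct._inv_affine[:3, :3].T + ct._inv_affine[:3, 3]
    upper = np.array(ct.shape, dtype=np.float64) - 1.0
    outside = np.any((vox < 0.0) | (vox > upper), axis=1)
    if np.all(outside):
        raise EmptySliceError("resampling plane lies entirely outside the volume")
    vals = ndimage.map_coordinates(
        ct.voxels, vox.T, order=1, mode="constant", cval=fill
    )
    vals = np.where(outside, fill, vals)
    return Slice2D(values=vals.reshape(ni, nj), spec=plane)
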