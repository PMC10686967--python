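"""Masked voxel grids: gray-matter masks, coordinate conversion, focus sampling.

The simulation places foci on a regular isotropic grid in MNI-style world
coordinates (mm).  The mask is either derived from an ICBM-style tissue
probability map (gray-matter probability strictly above a threshold) or a
built-in synthetic ellipsoid with MNI-like extents, which serves as the
canonical no-download fixture and contains the ground-truth location
(-30, -26, 58).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


class EmptyMaskError(ValueError):
    """The constructed mask contains no voxels."""


class OutOfGridError(ValueError):
    """A coordinate or index falls outside the grid."""


@dataclass
class VoxelGrid:
    """Regular isotropic voxel grid with a boolean mask.

    ``origin`` is the world-mm coordinate of voxel index (0, 0, 0); voxel
    (i, j, k) is centered at ``origin + voxel_size * (i, j, k)``.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: np.ndarray
    mask: np.ndarray

    _mask_indices: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.origin = np.asarray(self.origin, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.mask.shape != self.shape:
            raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise EmptyMaskError("mask contains no voxels")

    # --- derived ------------------------------------------------------------
    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_indices(self) -> np.ndarray:
        """(n_mask, 3) integer indices of mask voxels (cached)."""
        if self._mask_indices is None:
            self._mask_indices = np.argwhere(self.mask)
        return self._mask_indices

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    # --- conversions ----------------------------------------------------------
    def world_to_voxel(self, world: Sequence[float]) -> tuple[int, int, int]:
        """Nearest-voxel index of a world-mm coordinate; errors off-grid."""
        w = np.asarray(world, dtype=float)
        idx = np.rint((w - self.origin) / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise OutOfGridError(f"world coordinate {tuple(w)} outside grid")
        return tuple(int(i) for i in idx)

    def voxel_to_world(self, index: Sequence[int]) -> np.ndarray:
        idx = np.asarray(index, dtype=int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise OutOfGridError(f"voxel index {tuple(idx)} outside grid")
        return self.origin + self.voxel_size * idx

    def voxels_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(indices, dtype=float)

    def contains_world(self, world: Sequence[float]) -> bool:
        """True if the nearest voxel exists and is inside the mask."""
        try:
            idx = self.world_to_voxel(world)
        except OutOfGridError:
            return False
        return bool(self.mask[idx])

    # --- I/O ------------------------------------------------------------------
    def to_nifti(self, data: Optional[np.ndarray] = None) -> nib.Nifti1Image:
        """Wrap ``data`` (default: the mask) as a NIfTI image on this grid."""
        if data is None:
            data = self.mask.astype(np.uint8)
        return nib.Nifti1Image(np.asarray(data), self.affine)

    def save_map(self, data: np.ndarray, path: Union[str, Path]) -> None:
        nib.save(self.to_nifti(np.asarray(data, dtype=np.float32)), str(path))


def make_synthetic_mask(
    shape: Optional[tuple[int, int, int]] = None,
    semi_axes: tuple[float, float, float] = (72.0, 90.0, 72.0),
    voxel_size: float = 4.0,
    center: tuple[float, float, float] = (0.0, -18.0, 18.0),
) -> VoxelGrid:
    """Ellipsoidal brain-shaped mask on an MNI-like grid.

    With the default extents the mask has roughly the volume of a lenient
    gray-matter mask and contains the voxel nearest (-30, -26, 58).  A
    ``shape`` given explicitly centers the ellipsoid mid-grid.
    """
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("ellipsoid semi-axes must be positive")
    c = np.asarray(center, dtype=float)
    if shape is None:
        half = np.ceil(semi / voxel_size).astype(int)
        shape = tuple(2 * half + 1)
    shape = tuple(int(s) for s in shape)
    origin = c - voxel_size * (np.array(shape) - 1) / 2.0

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1) * voxel_size + origin
    r2 = np.sum(((world - c) / semi) ** 2, axis=-1)
    mask = r2 <= 1.0
    if not mask.any():
        raise EmptyMaskError("ellipsoid contains no voxel centers")
    return VoxelGrid(shape=shape, voxel_size=voxel_size, origin=origin, mask=mask)


def load_tpm_mask(
    path: Union[str, Path],
    gm_threshold: float = 0.10,
    voxel_size: float = 2.0,
) -> VoxelGrid:
    """Gray-matter mask from a tissue-probability-map NIfTI volume.

    A voxel enters the mask iff its gray-matter probability strictly exceeds
    ``gm_threshold``.  The probability volume is resampled to the requested
    isotropic resolution with nearest-neighbour interpolation *before*
    thresholding, which avoids smoothing-induced mask growth.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    if np.nanmin(data) < -1e-6 or np.nanmax(data) > 1 + 1e-6:
        raise ValueError("tissue probabilities must lie in [0, 1]")
    data = np.nan_to_num(data)

    src_aff = img.affine
    # world-axis-aligned bounding box of the source volume
    corners = np.array(np.meshgrid(*[[0, s - 1] for s in data.shape], indexing="ij"))
    corners = corners.reshape(3, -1).T
    world_corners = nib.affines.apply_affine(src_aff, corners)
    lo = world_corners.min(axis=0)
    hi = world_corners.max(axis=0)

    shape = tuple(int(np.floor((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
    origin = lo
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1) * voxel_size + origin
    src_idx = nib.affines.apply_affine(np.linalg.inv(src_aff), world.reshape(-1, 3))
    prob = map_coordinates(data, src_idx.T, order=0, mode="constant", cval=0.0)
    prob = prob.reshape(shape)

    mask = prob > gm_threshold  # strict: exactly-at-threshold voxels excluded
    if not mask.any():
        raise EmptyMaskError(f"no voxel exceeds gm probability {gm_threshold}")
    return VoxelGrid(shape=shape, voxel_size=voxel_size, origin=origin, mask=mask)


def sample_uniform_focus(grid: VoxelGrid, rng: np.random.Generator) -> np.ndarray:
    """One world-mm coordinate drawn uniformly over mask voxel centers."""
    return sample_uniform_foci(grid, 1, rng)[0]


def sample_uniform_foci(grid: VoxelGrid, k: int, rng: np.random.Generator) -> np.ndarray:
    """(k, 3) world-mm coordinates, each mask voxel equally likely."""
    if grid.n_mask == 0:  # unreachable: VoxelGrid forbids empty masks
        raise EmptyMaskError("cannot sample from an empty mask")
    if k < 1:
        raise ValueError("k must be >= 1")
    picks = rng.integers(0, grid.n_mask, size=k)
    return grid.voxels_to_world(grid.mask_indices[picks])
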