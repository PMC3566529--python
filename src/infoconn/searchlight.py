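"""Spherical voxel sets: seeds and roaming searchlights.

Radii are measured in voxel index units with the Euclidean norm on the
index grid (voxel anisotropy ignored): a radius-3 sphere contains exactly
123 lattice points, the searchlight volume used throughout.  Searchlights
centered near mask or volume edges are truncated, not discarded; the
surviving member count is recorded for downstream diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np
import scipy.sparse as sp


@dataclass
class VoxelSet:
    """A set of voxel coordinates, usually a (possibly truncated) sphere."""

    center: tuple[int, int, int]
    radius_vox: float
    members: np.ndarray  # (n, 3) int array

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64).reshape(-1, 3)
        self.center = tuple(int(c) for c in self.center)
        if self.radius_vox < 0:
            raise ValueError("radius_vox must be >= 0")

    @property
    def n_members(self) -> int:
        return len(self.members)

    def indicator(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean volume of the given shape, True at member voxels."""
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.members.T)] = True
        return out

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "VoxelSet":
        """Explicit voxel set from a binary mask; center = member nearest
        the centroid."""
        members = np.argwhere(np.asarray(mask) > 0)
        if len(members) == 0:
            raise ValueError("empty seed mask")
        centroid = members.mean(axis=0)
        center = members[np.argmin(((members - centroid) ** 2).sum(axis=1))]
        return cls(center=tuple(center), radius_vox=0.0, members=members)


@lru_cache(maxsize=32)
def _offsets_cached(radius_key: float) -> np.ndarray:
    r = float(radius_key)
    rint = int(np.floor(r))
    rng = range(-rint, rint + 1)
    out = [
        (di, dj, dk)
        for di in rng
        for dj in rng
        for dk in rng
        if di * di + dj * dj + dk * dk <= r * r
    ]
    return np.asarray(out, dtype=np.int64).reshape(-1, 3)


def sphere_offsets(radius_vox: float) -> np.ndarray:
    """All integer offsets (di,dj,dk) with squared norm <= radius^2.

    Deterministic lexicographic order; the boundary (squared norm exactly
    radius^2) is included.  Radius 3 yields 123 offsets.
    """
    if radius_vox < 0:
        raise ValueError("radius_vox must be >= 0")
    return _offsets_cached(float(radius_vox)).copy()


def build_sphere(
    center: tuple[int, int, int], radius_vox: float, mask: np.ndarray
) -> VoxelSet:
    """Sphere of the given radius at ``center``, truncated to mask and
    volume bounds."""
    mask = np.asarray(mask, dtype=bool)
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= s for c, s in zip(center, mask.shape)):
        raise ValueError(f"center {center} outside volume of shape {mask.shape}")
    pts = sphere_offsets(radius_vox) + np.asarray(center, dtype=np.int64)
    inb = np.all((pts >= 0) & (pts < np.asarray(mask.shape)), axis=1)
    pts = pts[inb]
    pts = pts[mask[tuple(pts.T)]]
    return VoxelSet(center=center, radius_vox=float(radius_vox), members=pts)


def iter_searchlights(
    mask: np.ndarray, radius_vox: float
) -> Iterator[tuple[tuple[int, int, int], VoxelSet]]:
    """One truncated sphere per masked voxel, in deterministic raster order."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    for center in np.argwhere(mask):
        c = tuple(int(v) for v in center)
        yield c, build_sphere(c, radius_vox, mask)


@dataclass
class SearchlightIndex:
    """Sparse membership of every masked-voxel-centered searchlight.

    ``matrix`` is a CSR matrix of shape (n_centers, n_masked_voxels) with a
    one wherever a masked voxel belongs to a center's (truncated) sphere;
    row sums give each searchlight's member count m.  Centers follow the
    raster order of ``np.argwhere(mask)``.
    """

    centers: np.ndarray  # (n_centers, 3)
    matrix: sp.csr_matrix
    mask: np.ndarray
    radius_vox: float
    n_members: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n_members = np.asarray(self.matrix.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    def map_to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place one value per center at its voxel in a full 3D volume."""
        out = np.full(self.mask.shape, fill, dtype=np.float64)
        out[tuple(self.centers.T)] = values
        return out

    def overlaps(self, seed: VoxelSet) -> np.ndarray:
        """Boolean per center: does its sphere share a voxel with the seed?"""
        seed_ind = np.zeros(self.mask.shape, dtype=np.float64)
        seed_ind[tuple(seed.members.T)] = 1.0
        return np.asarray(self.matrix @ seed_ind[self.mask]).ravel() > 0


def searchlight_index(mask: np.ndarray, radius_vox: float) -> SearchlightIndex:
    """Build the sparse searchlight membership matrix for a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    centers = np.argwhere(mask)
    n_centers = len(centers)
    vox_index = -np.ones(mask.shape, dtype=np.int64)
    vox_index[mask] = np.arange(n_centers)  # masked voxel -> column
    shape = np.asarray(mask.shape)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for off in sphere_offsets(radius_vox):
        pts = centers + off
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        cidx = vox_index[tuple(pts[ok].T)]
        in_mask = cidx >= 0
        rows.append(np.flatnonzero(ok)[in_mask])
        cols.append(cidx[in_mask])
    row = np.concatenate(rows)
    col = np.concatenate(cols)
    mat = sp.coo_matrix(
        (np.ones(len(row)), (row, col)), shape=(n_centers, n_centers)
    ).tocsr()
    return SearchlightIndex(
        centers=centers, matrix=mat, mask=mask, radius_vox=float(radius_vox)
    )
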