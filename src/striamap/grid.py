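"""Voxel grid geometry shared by all volumetric stages.

Conventions: voxel indexing is 0-based; world coordinates are in mm with the
affine ``world = index * voxel_size + origin`` (axis-aligned, no rotation).
Left/right hemisphere membership is decided by the sign of the first world
axis; the midline is the plane x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned 3-D voxel grid.

    Parameters
    ----------
    dims
        Number of voxels along each axis (all >= 1).
    voxel_size
        Edge length per axis in mm (default 2 mm isotropic, the working
        resolution of the diffusion data this pipeline emulates).
    origin
        World-mm coordinate of the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        if self.origin is None:
            # centre the grid on the world origin so the midline x = 0
            # bisects the volume between the two middle voxel columns
            origin = tuple(-vs[i] * (dims[i] - 1) / 2.0 for i in range(3))
            object.__setattr__(self, "origin", origin)
        else:
            object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world-mm coordinates of voxel centres."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world-mm points to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def world_coordinates(self) -> np.ndarray:
        """World-mm centre of every voxel, shape ``dims + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(d) for d in self.dims), indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        """Boolean: are integer voxel indices (..., 3) inside the grid?"""
        idx = np.asarray(idx)
        dims = np.asarray(self.dims)
        return np.all((idx >= 0) & (idx < dims), axis=-1)


def grids_compatible(a: VoxelGrid, b: VoxelGrid, atol: float = 1e-6) -> bool:
    return (
        a.dims == b.dims
        and np.allclose(a.voxel_size, b.voxel_size, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )
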