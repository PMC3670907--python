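"""Voxel-grid geometry shared by every volume type.

A :class:`VolumeGrid` couples integer voxel indices to world coordinates in
millimetres through a 4x4 affine (RAS+ convention, voxel-centre sampling:
the world position of voxel ``(i, j, k)`` is ``affine @ (i, j, k, 1)``).
All cross-volume operations in the package require either grid alignment
(same dims, affines equal to within ``ALIGN_TOL``) or an explicit transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: element-wise affine tolerance below which two grids count as aligned
ALIGN_TOL = 1e-4


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D voxel lattice.

    Parameters
    ----------
    dims
        Number of voxels along each axis; every entry >= 1.
    affine
        4x4 voxel-index -> world-mm transform; must be invertible and its
        column norms must equal the voxel size.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got shape {aff.shape}")
        if not np.allclose(aff[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("affine bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    # -- constructors ----------------------------------------------------
    @classmethod
    def isotropic(
        cls, dims: tuple[int, int, int], voxel_mm: float, origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ) -> "VolumeGrid":
        """Axis-aligned grid with cubic voxels of edge ``voxel_mm``."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = origin
        return cls(tuple(dims), aff)

    # -- derived geometry ------------------------------------------------
    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine's spatial columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    # -- coordinate mapping ----------------------------------------------
    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm (voxel-centre convention)."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm points (..., 3) to continuous voxel coordinates."""
        pts = np.asarray(pts, dtype=float)
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def contains_voxel(self, vox: np.ndarray) -> np.ndarray:
        """True where a continuous voxel coordinate lies on the lattice."""
        vox = np.asarray(vox, dtype=float)
        lo = vox >= -0.5
        hi = vox <= np.asarray(self.dims, dtype=float) - 0.5
        return np.all(lo & hi, axis=-1)

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``dims + (3,)``."""
        ii, jj, kk = np.meshgrid(*(np.arange(d) for d in self.dims), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1)
        return self.voxel_to_world(idx)

    # -- compatibility ---------------------------------------------------
    def aligned_with(self, other: "VolumeGrid", tol: float = ALIGN_TOL) -> bool:
        """Grids are aligned iff dims match and affines agree element-wise."""
        return self.dims == other.dims and bool(np.all(np.abs(self.affine - other.affine) < tol))


def require_aligned(a: VolumeGrid, b: VolumeGrid, what: str = "volumes") -> None:
    if not a.aligned_with(b):
        raise ValueError(f"{what} are not on aligned grids (dims {a.dims} vs {b.dims})")
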