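"""Group tensor-template construction: affine warping with PPD reorientation
and component-wise averaging across subjects.

Warping pulls each output voxel centre back through the inverse transform,
interpolates the six tensor components trilinearly, and then reorients the
interpolated tensor with the Preservation of Principal Direction (PPD) rule
using the transform's (spatially constant) linear part F:

    n1 = F e1 / ||F e1||
    n2 = normalize(F e2 - (F e2 . n1) n1)
    n3 = n1 x n2
    D' = sum_i lambda_i n_i n_i^T

PPD keeps eigenvalues exactly and, for a pure rotation R, reduces to the
conjugation R D R^T. Averaging is arithmetic per component (Euclidean, not
log-Euclidean), restricted per voxel to the subjects whose field of view
covers it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import VolumeGrid
from .volumes import ScalarVolume, TensorVolume, matrices_to_components


@dataclass(frozen=True)
class AffineTransform:
    """4x4 world-mm (subject) -> world-mm (template) transform."""

    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError(f"transform must be 4x4, got {mat.shape}")
        if not np.allclose(mat[3], [0, 0, 0, 1]):
            raise ValueError("transform bottom row must be (0, 0, 0, 1)")
        cond = np.linalg.cond(mat[:3, :3])
        if not np.isfinite(cond) or cond >= 1e6:
            raise ValueError(f"transform is singular or ill-conditioned (cond={cond:.3g})")
        mat = mat.copy()
        mat.flags.writeable = False
        object.__setattr__(self, "matrix", mat)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def rigid(cls, rotation: np.ndarray, translation: np.ndarray, center: np.ndarray | None = None) -> "AffineTransform":
        """Rigid transform rotating about ``center`` (world mm) then translating."""
        rotation = np.asarray(rotation, dtype=float)
        mat = np.eye(4)
        mat[:3, :3] = rotation
        t = np.asarray(translation, dtype=float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - rotation @ c
        mat[:3, 3] = t
        return cls(mat)

    @property
    def linear(self) -> np.ndarray:
        """The 3x3 linear part F (the transform's spatial Jacobian)."""
        return self.matrix[:3, :3]

    @property
    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.linear.T + self.matrix[:3, 3]


def ppd_reorient_components(comp: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Apply PPD reorientation with linear map ``F`` to (..., 6) components.

    Eigenvalues are preserved exactly; zero tensors pass through unchanged.
    """
    from .dti import principal_directions  # local import avoids cycle

    comp = np.asarray(comp, dtype=np.float64)
    evals, evecs = principal_directions(comp)  # rows e1,e2,e3
    e1 = evecs[..., 0, :]
    e2 = evecs[..., 1, :]

    f1 = e1 @ F.T
    n1 = f1 / np.maximum(np.linalg.norm(f1, axis=-1, keepdims=True), 1e-300)
    f2 = e2 @ F.T
    f2 = f2 - np.sum(f2 * n1, axis=-1, keepdims=True) * n1
    n2 = f2 / np.maximum(np.linalg.norm(f2, axis=-1, keepdims=True), 1e-300)
    n3 = np.cross(n1, n2)

    out = (
        evals[..., 0, None, None] * n1[..., :, None] * n1[..., None, :]
        + evals[..., 1, None, None] * n2[..., :, None] * n2[..., None, :]
        + evals[..., 2, None, None] * n3[..., :, None] * n3[..., None, :]
    )
    new = matrices_to_components(out)
    # keep exact zeros (background) as zeros
    zero = np.all(comp == 0.0, axis=-1)
    new[zero] = 0.0
    return new


def interpolate_volume(values: np.ndarray, voxel_coords: np.ndarray, order: int = 1) -> np.ndarray:
    """Trilinear (order=1) or nearest (order=0) sampling of a 3D array at
    continuous voxel coordinates (..., 3); points outside map to 0."""
    coords = np.moveaxis(np.asarray(voxel_coords, dtype=float), -1, 0)
    flat = coords.reshape(3, -1)
    out = map_coordinates(np.asarray(values, dtype=float), flat, order=order, mode="constant", cval=0.0)
    return out.reshape(voxel_coords.shape[:-1])


def warp_tensor_volume_ppd(
    tensors: TensorVolume, transform: AffineTransform, target_grid: VolumeGrid
) -> TensorVolume:
    """Resample a tensor volume onto ``target_grid`` through an affine
    subject->template transform, reorienting each tensor by PPD.

    The output coverage mask marks voxels whose pulled-back position falls
    inside the source field of view.
    """
    centers = target_grid.voxel_centers_world()  # dims + (3,)
    src_world = transform.inverse.apply(centers)
    src_vox = tensors.grid.world_to_voxel(src_world)

    comp = np.empty(target_grid.dims + (6,))
    for c in range(6):
        comp[..., c] = interpolate_volume(tensors.components[..., c], src_vox)
    s0 = interpolate_volume(tensors.s0, src_vox)

    inside = np.all(
        (src_vox >= 0) & (src_vox <= np.asarray(tensors.grid.dims, dtype=float) - 1), axis=-1
    )
    src_cov = interpolate_volume(tensors.coverage.astype(float), src_vox)
    coverage = inside & (src_cov > 0.999)

    comp = ppd_reorient_components(comp, transform.linear)
    comp[~coverage] = 0.0
    s0 = np.where(coverage, s0, 0.0)
    return TensorVolume(target_grid, comp, s0=s0, coverage=coverage)


def average_tensor_volumes(
    warped: Sequence[TensorVolume],
) -> tuple[TensorVolume, ScalarVolume]:
    """Arithmetic per-component mean of aligned tensor volumes.

    Voxels missing from some subjects (outside their field of view, per the
    coverage mask) are averaged over the subjects present there. Returns the
    template tensor volume and a coverage-count map.
    """
    if len(warped) == 0:
        raise ValueError("cannot average an empty list of tensor volumes")
    grid = warped[0].grid
    for w in warped[1:]:
        if not grid.aligned_with(w.grid):
            raise ValueError("tensor volumes are not on aligned grids")

    comp_sum = np.zeros(grid.dims + (6,))
    s0_sum = np.zeros(grid.dims)
    count = np.zeros(grid.dims)
    for w in warped:
        cov = w.coverage
        comp_sum += w.components * cov[..., None]
        s0_sum += w.s0 * cov
        count += cov
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(count[..., None] > 0, comp_sum / np.maximum(count, 1)[..., None], 0.0)
        s0 = np.where(count > 0, s0_sum / np.maximum(count, 1), 0.0)
    template = TensorVolume(grid, comp, s0=s0, coverage=count > 0)
    return template, ScalarVolume(grid, count)
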