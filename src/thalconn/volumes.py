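"""In-memory volume containers: scalar, mask, label, tensor and 4D DWI.

Every container pairs a data array with the :class:`~thalconn.grid.VolumeGrid`
it lives on; constructors validate the container's invariants (finite values,
strict binarity for masks, label-table coverage for label volumes, eigenvalue
sanity for tensors is enforced downstream by the fitting code).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grid import VolumeGrid


@dataclass
class ScalarVolume:
    """One finite real value per voxel (FA maps, probability maps, atlases)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.grid.dims:
            raise ValueError(f"values shape {vals.shape} != grid dims {self.grid.dims}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("scalar volume contains non-finite values")
        self.values = vals


@dataclass
class MaskVolume:
    """Strictly binary volume (seed, target and lesion masks)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.dims:
            raise ValueError(f"values shape {vals.shape} != grid dims {self.grid.dims}")
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask volume must be strictly binary, found values {uniq[:10]}")
            vals = vals.astype(bool)
        self.values = vals

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        """Mask volume as voxel count times voxel volume."""
        return self.n_true * self.grid.voxel_volume_mm3

    def voxel_indices(self) -> np.ndarray:
        """(K, 3) integer indices of the set voxels, in lexicographic order."""
        return np.argwhere(self.values)


@dataclass
class LabelVolume:
    """Non-negative integer labels per voxel; 0 is reserved for 'unassigned'.

    ``label_table`` maps every nonzero label that occurs in ``values`` to a
    human-readable target name such as ``"BA32"``.
    """

    grid: VolumeGrid
    values: np.ndarray
    label_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.dims:
            raise ValueError(f"values shape {vals.shape} != grid dims {self.grid.dims}")
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(vals)
            if not np.all(vals == rounded):
                raise ValueError("label volume values must be integers")
            vals = rounded.astype(np.int32)
        if vals.min() < 0:
            raise ValueError("label volume values must be non-negative")
        table = {int(k): str(v) for k, v in dict(self.label_table).items()}
        present = set(np.unique(vals).tolist()) - {0}
        missing = present - set(table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_table")
        self.values = vals.astype(np.int32)
        self.label_table = table

    def labels_present(self) -> list[int]:
        return sorted(set(np.unique(self.values).tolist()) - {0})


#: order of the six unique symmetric-tensor components stored per voxel
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

#: (row, col) index of each stored component in the full 3x3 tensor
_COMP_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor in mm^2/s.

    ``components`` holds the six unique entries (Dxx, Dxy, Dxz, Dyy, Dyz,
    Dzz) in an array of shape ``dims + (6,)``; ``s0`` is the per-voxel
    non-diffusion-weighted signal estimate; ``flags`` marks voxels that
    needed degenerate-input handling (signal clamping, negative-eigenvalue
    clipping); ``coverage`` marks voxels inside the data's field of view
    (used when averaging warped subjects into a template).
    """

    grid: VolumeGrid
    components: np.ndarray
    s0: np.ndarray | None = None
    flags: np.ndarray | None = None
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=np.float64)
        if comp.shape != self.grid.dims + (6,):
            raise ValueError(f"components shape {comp.shape} != grid dims + (6,)")
        if not np.all(np.isfinite(comp)):
            raise ValueError("tensor components contain non-finite values")
        self.components = comp
        if self.s0 is None:
            self.s0 = np.ones(self.grid.dims)
        else:
            s0 = np.asarray(self.s0, dtype=np.float64)
            if s0.shape != self.grid.dims:
                raise ValueError("s0 shape mismatch")
            self.s0 = s0
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
        if self.coverage is None:
            self.coverage = np.ones(self.grid.dims, dtype=bool)
        else:
            self.coverage = np.asarray(self.coverage, dtype=bool)

    def as_matrices(self) -> np.ndarray:
        """Expand the six components into full 3x3 tensors, shape dims+(3,3)."""
        return components_to_matrices(self.components)


def components_to_matrices(comp: np.ndarray) -> np.ndarray:
    """(..., 6) unique components -> (..., 3, 3) symmetric matrices."""
    comp = np.asarray(comp, dtype=np.float64)
    out = np.empty(comp.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(_COMP_IDX):
        out[..., i, j] = comp[..., c]
        out[..., j, i] = comp[..., c]
    return out


def matrices_to_components(mat: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) unique components."""
    mat = np.asarray(mat, dtype=np.float64)
    out = np.empty(mat.shape[:-2] + (6,))
    for c, (i, j) in enumerate(_COMP_IDX):
        out[..., c] = mat[..., i, j]
    return out


@dataclass
class DWIStack:
    """4D diffusion-weighted stack: one 3D frame per protocol entry."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 4 or data.shape[:3] != self.grid.dims:
            raise ValueError(f"DWI data shape {data.shape} incompatible with grid dims {self.grid.dims}")
        if not np.all(np.isfinite(data)):
            raise ValueError("DWI stack contains non-finite values")
        self.data = data

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])
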