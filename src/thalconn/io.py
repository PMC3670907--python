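"""On-disk formats: NIfTI volumes, FSL-style bval/bvec gradient tables.

Conventions: NIfTI-1, single-file ``.nii``/``.nii.gz``, RAS+ world frame,
0-based voxel indices with the world position of a voxel given by the header
affine applied to its integer index. Scalar data are stored as float32,
labels as int16, masks as uint8. Label tables travel in a ``.labels.json``
sidecar next to the label NIfTI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import VolumeGrid
from .volumes import DWIStack, LabelVolume, MaskVolume, ScalarVolume, TensorVolume


# ---------------------------------------------------------------------------
# diffusion protocol
# ---------------------------------------------------------------------------

@dataclass
class DiffusionProtocol:
    """Per-frame b-values (s/mm^2) and unit gradient directions.

    Directions of b=0 frames are arbitrary and stored as zeros. A valid
    protocol has at least one b=0 frame and at least six non-collinear
    weighted directions (otherwise the tensor design matrix is singular).
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=np.float64).ravel()
        g = np.asarray(self.directions, dtype=np.float64)
        if g.shape != (b.size, 3):
            raise ValueError(f"directions shape {g.shape} does not match {b.size} b-values")
        if np.any(b < 0):
            raise ValueError("negative b-values")
        weighted = b > 0
        if not np.any(~weighted):
            raise ValueError("protocol must contain at least one b=0 frame")
        g = g.copy()
        norms = np.linalg.norm(g[weighted], axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero gradient direction on a weighted frame")
        g[weighted] /= norms[:, None]
        g[~weighted] = 0.0
        # non-collinearity: the 6-column quadratic design must have full rank
        gw = g[weighted]
        design = np.column_stack([
            gw[:, 0] ** 2, 2 * gw[:, 0] * gw[:, 1], 2 * gw[:, 0] * gw[:, 2],
            gw[:, 1] ** 2, 2 * gw[:, 1] * gw[:, 2], gw[:, 2] ** 2,
        ])
        if gw.shape[0] < 6 or np.linalg.matrix_rank(design) < 6:
            raise ValueError("fewer than 6 non-collinear weighted directions")
        self.bvalues = b
        self.directions = g

    @property
    def n_frames(self) -> int:
        return int(self.bvalues.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))


def read_protocol(bval_path: str | Path, bvec_path: str | Path) -> DiffusionProtocol:
    """Read an FSL-dialect gradient table (bvec: one row per axis)."""
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError(f"bvec file must be 3xN or Nx3, got shape {bvecs.shape}")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous square case: FSL convention is one row per axis
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(f"{bvals.size} b-values but {bvecs.shape[0]} directions")
    return DiffusionProtocol(bvals, bvecs)


def write_protocol(protocol: DiffusionProtocol, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, protocol.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvec_path, protocol.directions.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    return VolumeGrid(tuple(int(d) for d in img.shape[:3]), np.asarray(img.affine))


def _check_finite(data: np.ndarray, path: str | Path) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains NaN or Inf voxels")


def read_volume(
    path: str | Path, expected_role: str = "scalar"
) -> ScalarVolume | MaskVolume | LabelVolume | DWIStack:
    """Read a NIfTI volume under a declared role.

    ``expected_role`` is one of ``scalar``, ``mask``, ``label`` or ``dwi``.
    Mask data must already be strictly 0/1 on disk (anything else is an
    error, never silently thresholded); label data must be integral, with
    names taken from a ``.labels.json`` sidecar when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    grid = _grid_from_img(img)
    data = np.asarray(img.get_fdata())
    _check_finite(data, path)
    if expected_role == "dwi":
        if data.ndim != 4:
            raise ValueError(f"{path}: role=dwi requires a 4D volume, got {data.ndim}D")
        return DWIStack(grid, data)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: role={expected_role} requires a 3D volume, got {data.ndim}D")
    if expected_role == "scalar":
        return ScalarVolume(grid, data)
    if expected_role == "mask":
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError(f"{path}: mask role requires strictly binary data, found {uniq[:10]}")
        return MaskVolume(grid, data.astype(bool))
    if expected_role == "label":
        sidecar = path.parent / (path.name.split(".")[0] + ".labels.json")
        if sidecar.exists():
            table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        else:
            table = {int(v): f"label{int(v)}" for v in np.unique(data) if v != 0}
        return LabelVolume(grid, np.rint(data).astype(np.int32), table)
    raise ValueError(f"unknown role {expected_role!r}")


def write_volume(volume, path: str | Path) -> Path:
    """Write a volume container to NIfTI-1; returns the path written.

    Storage dtypes: float32 for scalar/DWI/tensor data, uint8 for masks,
    int16 for labels. Label tables are written to a ``.labels.json``
    sidecar so that names survive the round trip.
    """
    path = Path(path)
    if isinstance(volume, ScalarVolume):
        data, dtype = volume.values, np.float32
    elif isinstance(volume, MaskVolume):
        data, dtype = volume.values.astype(np.uint8), np.uint8
    elif isinstance(volume, LabelVolume):
        data, dtype = volume.values.astype(np.int16), np.int16
    elif isinstance(volume, DWIStack):
        data, dtype = volume.data, np.float32
    else:
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), volume.grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    if isinstance(volume, LabelVolume):
        sidecar = path.parent / (path.name.split(".")[0] + ".labels.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in volume.label_table.items()}, indent=0))
    return path


# ---------------------------------------------------------------------------
# tensor volumes (6-component 4D NIfTI + companions)
# ---------------------------------------------------------------------------

def write_tensor_volume(tensors: TensorVolume, prefix: str | Path) -> dict[str, Path]:
    """Write a tensor volume as ``<prefix>_tensor.nii.gz`` (4D, 6 frames in
    Dxx,Dxy,Dxz,Dyy,Dyz,Dzz order) plus ``_s0``, ``_flags`` and ``_coverage``
    companions."""
    prefix = Path(prefix)
    paths: dict[str, Path] = {}
    img = nib.Nifti1Image(tensors.components.astype(np.float32), tensors.grid.affine)
    paths["tensor"] = Path(f"{prefix}_tensor.nii.gz")
    nib.save(img, paths["tensor"])
    paths["s0"] = write_volume(ScalarVolume(tensors.grid, tensors.s0), f"{prefix}_s0.nii.gz")
    if tensors.flags is not None:
        paths["flags"] = write_volume(
            MaskVolume(tensors.grid, tensors.flags), f"{prefix}_flags.nii.gz"
        )
    paths["coverage"] = write_volume(
        MaskVolume(tensors.grid, tensors.coverage), f"{prefix}_coverage.nii.gz"
    )
    return paths


def read_tensor_volume(prefix: str | Path) -> TensorVolume:
    """Read a tensor volume written by :func:`write_tensor_volume`."""
    prefix = Path(prefix)
    img = nib.load(f"{prefix}_tensor.nii.gz")
    grid = _grid_from_img(img)
    comp = np.asarray(img.get_fdata())
    if comp.ndim != 4 or comp.shape[3] != 6:
        raise ValueError(f"{prefix}_tensor.nii.gz is not a 6-component tensor volume")
    _check_finite(comp, prefix)
    s0 = read_volume(f"{prefix}_s0.nii.gz", "scalar").values
    flags_path = Path(f"{prefix}_flags.nii.gz")
    flags = read_volume(flags_path, "mask").values if flags_path.exists() else None
    cov_path = Path(f"{prefix}_coverage.nii.gz")
    coverage = read_volume(cov_path, "mask").values if cov_path.exists() else None
    return TensorVolume(grid, comp, s0=s0, flags=flags, coverage=coverage)


def read_affine_transform(path: str | Path) -> np.ndarray:
    """Read a 4x4 world->world affine from a whitespace text file."""
    mat = np.loadtxt(path, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return mat
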