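"""Diffusion-tensor estimation and derived quantities.

The tensor is fitted voxel-wise by unweighted log-linear least squares on
the mono-exponential signal model ``ln S = ln S0 - b g^T D g``. Fractional
anisotropy follows the standard normalised-deviatoric definition

    FA = sqrt(3/2) * ||D - (tr D / 3) I||_F / ||D||_F

and is 0 for the zero tensor by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DiffusionProtocol
from .volumes import (
    DWIStack,
    MaskVolume,
    ScalarVolume,
    TensorVolume,
    components_to_matrices,
    matrices_to_components,
)

#: fraction of the mean b0 signal used as the log-transform floor
SIGNAL_FLOOR_FRACTION = 1e-6


def design_matrix(protocol: DiffusionProtocol) -> np.ndarray:
    """(F, 7) design for log-linear fitting: columns are
    [1, -b gx^2, -2b gx gy, -2b gx gz, -b gy^2, -2b gy gz, -b gz^2],
    so that ``A @ [ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz] = ln S``."""
    b = protocol.bvalues
    g = protocol.directions
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -b * g[:, 1] ** 2,
        -2 * b * g[:, 1] * g[:, 2],
        -b * g[:, 2] ** 2,
    ])


def fit_tensor_lls(
    dwi: DWIStack,
    protocol: DiffusionProtocol,
    brain_mask: MaskVolume | None = None,
) -> TensorVolume:
    """Fit the diffusion tensor voxel-wise by log-linear least squares.

    Signals are clamped to ``SIGNAL_FLOOR_FRACTION`` times the mean b0
    signal before the log transform; clamped voxels are flagged. After the
    fit, negative eigenvalues are clipped to zero (eigenvectors kept) and
    those voxels flagged too. Voxels outside ``brain_mask`` get a zero
    tensor and zero s0.
    """
    if dwi.n_frames != protocol.n_frames:
        raise ValueError(f"DWI has {dwi.n_frames} frames but protocol {protocol.n_frames}")
    if dwi.n_frames < 7:
        raise ValueError("need at least 7 frames to fit 6 tensor components + s0")
    grid = dwi.grid
    if brain_mask is None:
        mask = np.ones(grid.dims, dtype=bool)
    else:
        if not grid.aligned_with(brain_mask.grid):
            raise ValueError("brain mask grid is not aligned with the DWI grid")
        mask = brain_mask.values

    signals = dwi.data[mask]  # (V, F)
    b0_mean = float(np.mean(signals[:, protocol.b0_mask])) if signals.size else 1.0
    floor = max(SIGNAL_FLOOR_FRACTION * max(b0_mean, 0.0), np.finfo(float).tiny)
    clamped = signals < floor
    signals = np.maximum(signals, floor)

    A = design_matrix(protocol)
    # pinv raises implicitly on rank deficiency via the protocol validator;
    # a deliberate singular design is still caught here
    if np.linalg.matrix_rank(A) < 7:
        raise np.linalg.LinAlgError("singular design matrix (collinear directions)")
    coef = np.log(signals) @ np.linalg.pinv(A).T  # (V, 7)

    comp = np.zeros(grid.dims + (6,))
    s0 = np.zeros(grid.dims)
    flags = np.zeros(grid.dims, dtype=bool)
    comp[mask] = coef[:, 1:]
    s0[mask] = np.exp(coef[:, 0])
    flags[mask] = clamped.any(axis=1)

    # clip negative eigenvalues to zero, keeping eigenvectors
    mats = components_to_matrices(comp[mask])
    evals, evecs = np.linalg.eigh(mats)
    negative = evals < -1e-15  # roundoff-sized negatives are not QC events
    if np.any(negative):
        evals = np.maximum(evals, 0.0)
        rebuilt = np.einsum("vij,vj,vkj->vik", evecs, evals, evecs)
        bad = negative.any(axis=1)
        masked_comp = comp[mask]
        masked_comp[bad] = matrices_to_components(rebuilt[bad])
        comp[mask] = masked_comp
        masked_flags = flags[mask]
        masked_flags |= bad
        flags[mask] = masked_flags

    return TensorVolume(grid, comp, s0=s0, flags=flags, coverage=mask.copy())


def fa_from_components(comp: np.ndarray) -> np.ndarray:
    """FA for an array (..., 6) of tensor components; 0 for zero tensors."""
    comp = np.asarray(comp, dtype=np.float64)
    dxx, dxy, dxz, dyy, dyz, dzz = (comp[..., i] for i in range(6))
    trace = dxx + dyy + dzz
    md = trace / 3.0
    # squared Frobenius norms of D and of its deviatoric part
    norm2 = dxx**2 + dyy**2 + dzz**2 + 2 * (dxy**2 + dxz**2 + dyz**2)
    dev2 = (dxx - md) ** 2 + (dyy - md) ** 2 + (dzz - md) ** 2 + 2 * (dxy**2 + dxz**2 + dyz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    # FA is scale-invariant, so roundoff-sized tensors would get arbitrary
    # values; anything below 1e-12 mm^2/s in norm counts as the zero tensor
    fa = np.where(norm2 > 1e-24, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa(tensors: TensorVolume) -> ScalarVolume:
    """Fractional-anisotropy map of a tensor volume (values in [0, 1])."""
    return ScalarVolume(tensors.grid, fa_from_components(tensors.components))


def fa_from_eigenvalues(evals) -> float:
    """Closed-form FA from three eigenvalues (any order)."""
    l1, l2, l3 = (float(v) for v in evals)
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    if den == 0.0:
        return 0.0
    return float(np.sqrt(0.5 * num / den))


@dataclass
class EigenSystem:
    """Eigenvalues in descending order with orthonormal eigenvectors.

    ``eigenvalues[i]`` pairs with row ``eigenvectors[i]``. Sign convention:
    each eigenvector's largest-magnitude component is positive, which makes
    the decomposition deterministic up to exact ties.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[0]


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvectors (rows ..., i, :) so the largest-|.| entry is positive."""
    idx = np.argmax(np.abs(vecs), axis=-1, keepdims=True)
    lead = np.take_along_axis(vecs, idx, axis=-1)
    return vecs * np.where(lead < 0, -1.0, 1.0)


def eigendecompose(tensor: np.ndarray) -> EigenSystem:
    """Eigensystem of one symmetric 3x3 tensor, descending eigenvalues."""
    tensor = np.asarray(tensor, dtype=np.float64)
    if tensor.shape == (6,):
        tensor = components_to_matrices(tensor)
    if tensor.shape != (3, 3):
        raise ValueError(f"expected a 3x3 tensor or 6 components, got {tensor.shape}")
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order].T  # rows are eigenvectors
    return EigenSystem(evals, _fix_signs(evecs))


def principal_directions(comp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched eigensystem for (..., 6) components.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvalues descending
    along the last axis and eigenvectors as rows ``[..., i, :]``, sign-fixed
    as in :func:`eigendecompose`.
    """
    mats = components_to_matrices(comp)
    evals, evecs = np.linalg.eigh(mats)
    evals = evals[..., ::-1]
    evecs = np.swapaxes(evecs[..., ::-1], -1, -2)  # rows are eigenvectors
    return evals, _fix_signs(evecs)
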