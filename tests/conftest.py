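"""Shared fixtures: diffusion protocols and synthetic phantoms."""

from __future__ import annotations

import numpy as np
import pytest

import thalconn as tc


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random 3x3 rotation via QR with positive diagonal."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def random_spd_tensor(rng: np.random.Generator, scale: float = 1e-3) -> np.ndarray:
    """Random symmetric positive-definite tensor with diffusivity-like scale."""
    R = random_rotation(rng)
    evals = rng.uniform(0.2, 2.0, size=3) * scale
    return R @ np.diag(evals) @ R.T


def single_bundle_spec(
    dims=(20, 30, 20), voxel_mm: float = 2.3, radius_vox: float = 2.5
) -> tc.PhantomSpec:
    """One straight bundle along +y joining a seed slab to one target block."""
    grid = tc.VolumeGrid.isotropic(dims, voxel_mm)
    nx, ny, nz = dims
    cx, cz = (nx - 1) / 2, (nz - 1) / 2
    radius = radius_vox * voxel_mm
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    r = np.hypot(ii - cx, kk - cz) * voxel_mm

    seed = np.zeros(dims, dtype=bool)
    seed[1 : nx - 1, 4:7, 1 : nz - 1] = True
    patch = (r < radius) & (jj >= 4) & (jj <= 6) & seed
    targets = np.zeros(dims, dtype=np.int32)
    targets[:, ny - 6 : ny - 2, :][r[:, ny - 6 : ny - 2, :] < 3.2 * voxel_mm] = 1

    start = grid.voxel_to_world([cx, 3.0, cz])
    end = grid.voxel_to_world([cx, ny - 4.0, cz])
    bundle = tc.BundleSpec(
        name="T1",
        centerline=np.stack([start, 0.5 * (start + end), end]),
        radius_mm=radius,
        seed_patch=tc.MaskVolume(grid, patch),
        target_label=1,
    )
    return tc.PhantomSpec(
        grid=grid,
        bundles=[bundle],
        seed_region=tc.MaskVolume(grid, seed),
        targets=tc.LabelVolume(grid, targets, {1: "T1"}),
    )


@pytest.fixture(scope="session")
def protocol() -> tc.DiffusionProtocol:
    """81 weighted directions at b=1000 s/mm^2 plus 9 b=0 frames."""
    return tc.make_protocol(81, 9, 1000.0)


@pytest.fixture(scope="session")
def small_protocol() -> tc.DiffusionProtocol:
    """Reduced 30+3 protocol for cheap synthesis in unit tests."""
    return tc.make_protocol(30, 3, 1000.0)


@pytest.fixture(scope="session")
def default_phantom():
    """Default three-bundle phantom with its tensor field and ground truth."""
    spec = tc.default_phantom_spec()
    tensors, truth = tc.build_tensor_phantom(spec)
    return spec, tensors, truth


@pytest.fixture(scope="session")
def bundle_phantom():
    """Small single-bundle phantom with its tensor field and ground truth."""
    spec = single_bundle_spec()
    tensors, truth = tc.build_tensor_phantom(spec)
    return spec, tensors, truth
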