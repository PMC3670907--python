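"""Synthetic diffusion phantoms: fiber bundles with known seed-to-target
connectivity, multi-subject cohorts with Rician noise and rigid jitter, and
ellipsoidal lesion masks.

The phantom emulates the statistical structure the analysis assumes: a
cohort of healthy-control tensor volumes in near-common space containing
coherent fiber bundles that join distinct sub-patches of a subcortical seed
region (standing in for the thalamus) to distinct labeled target regions
(standing in for prefrontal Brodmann areas), plus focal lesions of known
placement and volume. Inside a bundle tube the tensor is axially symmetric
with its principal eigenvector along the local centerline tangent; outside
it is isotropic. A single-tensor model cannot represent crossings, so where
tubes overlap the last-listed bundle wins (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree

from .grid import VolumeGrid, require_aligned
from .io import DiffusionProtocol
from .template import AffineTransform, warp_tensor_volume_ppd
from .volumes import DWIStack, LabelVolume, MaskVolume, TensorVolume

logger = logging.getLogger(__name__)

#: default diffusivities, mm^2/s — typical healthy white matter (axial/radial)
#: and gray-matter-like isotropic background
DEFAULT_AXIAL = 1.7e-3
DEFAULT_RADIAL = 0.3e-3
DEFAULT_BACKGROUND = 0.8e-3


@dataclass
class BundleSpec:
    """One synthetic fiber bundle.

    The tube of radius ``radius_mm`` around the (smoothly interpolated)
    centerline carries an axially symmetric tensor with eigenvalues
    (axial, radial, radial) and principal eigenvector along the local
    tangent. ``seed_patch`` is the sub-block of the seed region the bundle
    emanates from; its voxels receive ``target_label`` in the ground truth.
    """

    name: str
    centerline: np.ndarray  # (K, 3) world-mm control points
    radius_mm: float
    seed_patch: MaskVolume
    target_label: int
    axial_diffusivity: float = DEFAULT_AXIAL
    radial_diffusivity: float = DEFAULT_RADIAL

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("centerline needs at least two 3D control points")
        self.centerline = pts
        if self.radius_mm <= 0:
            raise ValueError("bundle radius must be positive")
        if not (self.axial_diffusivity >= self.radial_diffusivity > 0):
            raise ValueError("need axial >= radial > 0 diffusivities")
        if self.target_label <= 0:
            raise ValueError("target_label must be a positive integer")


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic connectivity phantom."""

    grid: VolumeGrid
    bundles: list[BundleSpec]
    seed_region: MaskVolume
    targets: LabelVolume
    background_diffusivity: float = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        require_aligned(self.grid, self.seed_region.grid, "seed region and phantom grid")
        require_aligned(self.grid, self.targets.grid, "targets and phantom grid")
        if self.background_diffusivity <= 0:
            raise ValueError("background diffusivity must be positive")
        for b in self.bundles:
            require_aligned(self.grid, b.seed_patch.grid, f"bundle {b.name} seed patch")
            if np.any(b.seed_patch.values & ~self.seed_region.values):
                raise ValueError(f"bundle {b.name} seed patch leaves the seed region")


@dataclass
class CohortSpec:
    """Synthetic healthy cohort: per-subject Rician noise and rigid jitter."""

    n_subjects: int = 19
    snr_b0: float = 20.0
    rotation_max_deg: float = 2.0
    translation_max_mm: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be positive (use np.inf for noiseless)")


@dataclass
class LesionSpec:
    """Axis-aligned ellipsoidal lesion in world coordinates."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    side_label: str = ""

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("lesion semi-axes must be positive")


# ---------------------------------------------------------------------------
# tensor phantom
# ---------------------------------------------------------------------------

def _resample_centerline(points: np.ndarray, spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length resample a piecewise-cubic interpolation of the control
    points; returns (samples, unit tangents)."""
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("degenerate centerline (zero length)")
    k = min(3, points.shape[0] - 1)
    spline = make_interp_spline(chord, points, k=k)
    n = max(int(np.ceil(chord[-1] / spacing_mm)) + 1, 2)
    t = np.linspace(0.0, chord[-1], n)
    samples = spline(t)
    tangents = spline.derivative()(t)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return samples, tangents


def build_tensor_phantom(spec: PhantomSpec) -> tuple[TensorVolume, LabelVolume]:
    """Rasterise a phantom spec into a tensor volume plus ground truth.

    Ground truth labels each seed voxel with the target label of the bundle
    whose seed patch contains it (0 elsewhere). Overlapping tubes resolve to
    the last-listed bundle; the overlap voxel count is logged.
    """
    grid = spec.grid
    comp = np.zeros(grid.dims + (6,))
    iso = spec.background_diffusivity
    comp[..., 0] = iso  # Dxx
    comp[..., 3] = iso  # Dyy
    comp[..., 5] = iso  # Dzz

    centers = grid.voxel_centers_world().reshape(-1, 3)
    claimed = np.zeros(grid.n_voxels, dtype=bool)
    n_overlap = 0
    spacing = 0.25 * float(np.min(grid.voxel_size))
    for bundle in spec.bundles:
        samples, tangents = _resample_centerline(bundle.centerline, spacing)
        tree = cKDTree(samples)
        dist, nearest = tree.query(centers, workers=1)
        inside = dist < bundle.radius_mm
        n_overlap += int(np.count_nonzero(inside & claimed))
        t = tangents[nearest[inside]]
        ax, rad = bundle.axial_diffusivity, bundle.radial_diffusivity
        # D = rad * I + (ax - rad) * t t^T
        d = np.zeros((t.shape[0], 6))
        d[:, 0] = rad + (ax - rad) * t[:, 0] ** 2
        d[:, 1] = (ax - rad) * t[:, 0] * t[:, 1]
        d[:, 2] = (ax - rad) * t[:, 0] * t[:, 2]
        d[:, 3] = rad + (ax - rad) * t[:, 1] ** 2
        d[:, 4] = (ax - rad) * t[:, 1] * t[:, 2]
        d[:, 5] = rad + (ax - rad) * t[:, 2] ** 2
        flat = comp.reshape(-1, 6)
        flat[inside] = d
        claimed |= inside
    if n_overlap:
        logger.warning("bundle tubes overlap in %d voxels; last-listed bundle wins", n_overlap)

    truth = np.zeros(grid.dims, dtype=np.int32)
    table: dict[int, str] = {}
    for bundle in spec.bundles:
        truth[bundle.seed_patch.values] = bundle.target_label
        table[bundle.target_label] = spec.targets.label_table.get(
            bundle.target_label, bundle.name
        )
    tensors = TensorVolume(grid, comp)
    return tensors, LabelVolume(grid, truth, table)


# ---------------------------------------------------------------------------
# DWI synthesis
# ---------------------------------------------------------------------------

def synthesize_dwi(
    tensors: TensorVolume,
    protocol: DiffusionProtocol,
    s0: float = 1000.0,
    snr_b0: float = np.inf,
    rng_seed: int | np.random.Generator = 0,
) -> DWIStack:
    """Mono-exponential DWI synthesis ``S = s0 exp(-b g^T D g)`` with
    optional Rician noise of scale ``s0 / snr_b0`` (noiseless at infinite
    SNR). Noise is drawn per frame from magnitude-MRI statistics:
    ``sqrt((S + n1)^2 + n2^2)`` with iid Gaussian n1, n2."""
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if not snr_b0 > 0:
        raise ValueError("snr_b0 must be positive (np.inf for noiseless)")
    b = protocol.bvalues
    g = protocol.directions
    # b g^T D g per frame, from the 6 unique components
    quad = np.stack([
        g[:, 0] ** 2, 2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
        g[:, 1] ** 2, 2 * g[:, 1] * g[:, 2], g[:, 2] ** 2,
    ], axis=1)  # (F, 6)
    exponent = -np.einsum("...c,fc->...f", tensors.components, quad * b[:, None])
    signal = s0 * np.exp(exponent)
    if np.isfinite(snr_b0):
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        sigma = s0 / snr_b0
        n1 = rng.normal(0.0, sigma, size=signal.shape)
        n2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DWIStack(tensors.grid, signal)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _random_rigid(
    rng: np.random.Generator, rotation_max_deg: float, translation_max_mm: float, center: np.ndarray
) -> AffineTransform:
    """Rigid jitter: rotation by a uniform angle <= max about a random axis
    through ``center``, plus a uniform translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-rotation_max_deg, rotation_max_deg))
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-translation_max_mm, translation_max_mm, size=3)
    return AffineTransform.rigid(R, t, center=center)


def generate_cohort(
    spec: PhantomSpec,
    cohort: CohortSpec,
    protocol: DiffusionProtocol,
    s0: float = 1000.0,
) -> list[tuple[DWIStack, AffineTransform]]:
    """Simulate a cohort of subjects from one phantom.

    Each subject is the phantom tensor field resampled under a small random
    rigid template->subject transform (with PPD reorientation), converted to
    DWI with independent Rician noise. The returned transform per subject is
    the subject->template map (the recorded inverse). Output is a pure
    function of the specs and ``cohort.rng_seed``.
    """
    tensors, _ = build_tensor_phantom(spec)
    grid = spec.grid
    center = grid.voxel_to_world((np.asarray(grid.dims, dtype=float) - 1) / 2)

    # bundle extent check: jitter must not push any tube off the grid
    margin = max((b.radius_mm for b in spec.bundles), default=0.0)
    samples = [
        _resample_centerline(b.centerline, float(np.min(grid.voxel_size)))[0]
        for b in spec.bundles
    ]

    out: list[tuple[DWIStack, AffineTransform]] = []
    for s in range(cohort.n_subjects):
        rng = np.random.default_rng([int(cohort.rng_seed) % (2**31), s])
        to_subject = _random_rigid(rng, cohort.rotation_max_deg, cohort.translation_max_mm, center)
        for pts in samples:
            vox = grid.world_to_voxel(to_subject.apply(pts))
            pad = margin / np.min(grid.voxel_size)
            if np.any(vox < -0.5 + pad - 1e-9) or np.any(
                vox > np.asarray(grid.dims) - 0.5 - pad + 1e-9
            ):
                raise ValueError(
                    f"subject {s}: rigid jitter pushes a bundle off the grid; "
                    "reduce rotation_max_deg/translation_max_mm"
                )
        subject_tensors = warp_tensor_volume_ppd(tensors, to_subject, grid)
        # outside-FOV voxels revert to isotropic background rather than zero
        bg = spec.background_diffusivity
        missing = ~subject_tensors.coverage
        for c, v in zip(range(6), (bg, 0.0, 0.0, bg, 0.0, bg)):
            subject_tensors.components[missing, c] = v
        dwi = synthesize_dwi(subject_tensors, protocol, s0=s0, snr_b0=cohort.snr_b0, rng_seed=rng)
        out.append((dwi, to_subject.inverse))
    return out


# ---------------------------------------------------------------------------
# acquisition protocol
# ---------------------------------------------------------------------------

def make_protocol(
    n_weighted: int = 81, n_b0: int = 9, bval: float = 1000.0
) -> DiffusionProtocol:
    """Deterministic diffusion protocol: ``n_b0`` b=0 frames followed by
    ``n_weighted`` weighted frames at ``bval`` with directions spread over
    the hemisphere by a spherical Fibonacci lattice (guaranteed
    non-collinear for n >= 6). Defaults mirror a typical 3T protocol of 81
    non-collinear directions at b = 1000 s/mm^2 plus nine b=0 images."""
    if n_weighted < 6 or n_b0 < 1:
        raise ValueError("need at least 6 weighted directions and 1 b=0 frame")
    i = np.arange(n_weighted)
    z = (i + 0.5) / n_weighted  # upper hemisphere avoids antipodal duplicates
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvalues = np.concatenate([np.zeros(n_b0), np.full(n_weighted, float(bval))])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionProtocol(bvalues, directions)


# ---------------------------------------------------------------------------
# lesion masks
# ---------------------------------------------------------------------------

def generate_lesion_mask(lesion: LesionSpec, grid: VolumeGrid) -> MaskVolume:
    """Binary mask of voxels whose centre lies inside the ellipsoid."""
    centers = grid.voxel_centers_world()
    rel = (centers - np.asarray(lesion.center_mm)) / np.asarray(lesion.semi_axes_mm)
    inside = np.sum(rel**2, axis=-1) <= 1.0
    if not np.any(inside):
        raise ValueError("lesion ellipsoid contains no voxel centres on this grid")
    return MaskVolume(grid, inside)


# ---------------------------------------------------------------------------
# default three-bundle phantom
# ---------------------------------------------------------------------------

def default_phantom_spec(
    dims: tuple[int, int, int] = (40, 60, 40),
    voxel_mm: float = 2.3,
    target_names: Sequence[str] = ("BA6", "BA9", "BA32"),
) -> PhantomSpec:
    """Three parallel straight bundles joining three disjoint seed patches
    to three disjoint target blocks.

    The default grid is 40x60x40 at 2.3 mm isotropic (a typical DWI
    acquisition resolution); pass ``voxel_mm=1.0`` with scaled dims for a
    template-resolution variant. Bundles run along +y from a seed slab near
    y~10 to target blocks near the far y face; patches are tube cross
    sections strictly interior to the tube so that every patch voxel has
    anisotropic support around it.
    """
    grid = VolumeGrid.isotropic(dims, voxel_mm)
    nx, ny, nz = dims
    xs = [0.25, 0.5, 0.75]  # bundle x positions as grid fractions
    z0 = (nz - 1) / 2
    y_seed_lo, y_seed_hi = 9, 12               # seed slab voxel range (incl.)
    y_tube_end = ny - 10                       # tube continues into targets
    y_tgt_lo, y_tgt_hi = ny - 12, ny - 8
    radius = 3.0 * voxel_mm

    seed = np.zeros(dims, dtype=bool)
    seed[2 : nx - 2, y_seed_lo : y_seed_hi + 1, int(z0) - 4 : int(z0) + 5] = True

    targets = np.zeros(dims, dtype=np.int32)
    table = {i + 1: str(n) for i, n in enumerate(target_names)}
    bundles: list[BundleSpec] = []
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    cxs = [round(fx * (nx - 1)) for fx in xs]
    # target blocks span cx +- 3 columns, so spacing >= 7 keeps them disjoint
    if min(b - a for a, b in zip(cxs, cxs[1:])) < 7:
        raise ValueError(f"grid too small in x for disjoint bundles/targets: dims={dims}")
    for i, cx in enumerate(cxs):
        label = i + 1
        targets[
            max(cx - 3, 0) : cx + 4, y_tgt_lo : y_tgt_hi + 1, int(z0) - 3 : int(z0) + 4
        ] = label
        start = grid.voxel_to_world([cx, y_seed_lo - 1, z0])
        end = grid.voxel_to_world([cx, y_tube_end, z0])
        mid = 0.5 * (start + end)
        # patch = tube cross-section within the seed slab (same strict-<
        # rule as the rasteriser), so ground truth matches exactly what
        # the bundle connects
        r_vox = np.hypot(ii - cx, kk - z0) * voxel_mm
        patch = (
            (r_vox < radius)
            & (jj >= y_seed_lo)
            & (jj <= y_seed_hi)
            & seed
        )
        bundles.append(
            BundleSpec(
                name=str(target_names[i]),
                centerline=np.stack([start, mid, end]),
                radius_mm=radius,
                seed_patch=MaskVolume(grid, patch),
                target_label=label,
            )
        )
    return PhantomSpec(
        grid=grid,
        bundles=bundles,
        seed_region=MaskVolume(grid, seed),
        targets=LabelVolume(grid, targets, table),
    )
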