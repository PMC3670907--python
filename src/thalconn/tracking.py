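"""Probabilistic (PICo-style) streamline tractography on a tensor volume.

Connection probabilities are estimated by Monte Carlo: from every seed
voxel, N streamlines are propagated step by step, each step drawing its
direction from an axially symmetric dispersion cone around the local
principal eigenvector. The cone's angular spread widens as fractional
anisotropy drops — low anisotropy means low confidence in the estimated
fiber direction — via a linear FA -> sigma map between ``sigma_min_deg``
(FA=1) and ``sigma_max_deg`` (FA=0). The probability of connection of a
seed voxel to a target is the fraction of its streamlines that visit any
voxel carrying that target's label (a streamline may count toward several
targets).

Randomness: one master seed; each seed voxel gets an independent substream
``default_rng([master_seed, voxel_counter])`` where ``voxel_counter`` is
the voxel's position in the lexicographically sorted seed-voxel list, so
results do not depend on processing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dti import principal_directions
from .grid import VolumeGrid, require_aligned
from .template import interpolate_volume
from .volumes import LabelVolume, MaskVolume, ScalarVolume, TensorVolume

TERM_LEFT_GRID = "left-grid"
TERM_FA_FLOOR = "fa-floor"
TERM_CURVATURE = "curvature"
TERM_MAX_STEPS = "max-steps"
_REASONS = (TERM_LEFT_GRID, TERM_FA_FLOOR, TERM_CURVATURE, TERM_MAX_STEPS)


@dataclass(frozen=True)
class TrackingConfig:
    """Tunable tracking parameters.

    ``step_mm=None`` resolves per grid to ``max(1.0, half the smallest
    voxel edge)``: 1.0 mm on a 1 mm template, half a voxel on coarser
    acquisition grids. Defaults otherwise follow conventional
    single-tensor probabilistic-tractography practice: 2000 step cap, 80
    degree per-step curvature limit, FA floor 0.1, 1000 samples per seed
    voxel, dispersion between 2 and 40 degrees.
    """

    step_mm: float | None = None
    max_steps: int = 2000
    curvature_limit_deg: float = 80.0
    fa_floor: float = 0.1
    samples_per_seed: int = 1000
    sigma_min_deg: float = 2.0
    sigma_max_deg: float = 40.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm is not None and not self.step_mm > 0:
            raise ValueError("step_mm must be positive")
        if not (0 < self.curvature_limit_deg <= 90):
            raise ValueError("curvature_limit_deg must be in (0, 90]")
        if not (0 <= self.fa_floor < 1):
            raise ValueError("fa_floor must be in [0, 1)")
        if self.samples_per_seed < 1:
            raise ValueError("samples_per_seed must be >= 1")
        if self.sigma_min_deg > self.sigma_max_deg:
            raise ValueError("sigma_min_deg must be <= sigma_max_deg")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    def resolved_step_mm(self, grid: VolumeGrid) -> float:
        if self.step_mm is not None:
            return float(self.step_mm)
        return max(1.0, 0.5 * float(np.min(grid.voxel_size)))


def dispersion_from_fa(fa, config: TrackingConfig):
    """Angular dispersion (degrees) as a function of FA: linear from
    ``sigma_max_deg`` at FA=0 down to ``sigma_min_deg`` at FA=1."""
    fa = np.clip(np.asarray(fa, dtype=float), 0.0, 1.0)
    sigma = config.sigma_max_deg + (config.sigma_min_deg - config.sigma_max_deg) * fa
    return sigma if sigma.ndim else float(sigma)


def _orthonormal_frame(e1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to each row of e1."""
    helper = np.zeros_like(e1)
    smallest = np.argmin(np.abs(e1), axis=-1)
    helper[np.arange(e1.shape[0]), smallest] = 1.0
    u = np.cross(e1, helper)
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    v = np.cross(e1, u)
    return u, v


def _directions_from_variates(
    e1: np.ndarray, sigma_deg: np.ndarray, previous: np.ndarray,
    theta_std: np.ndarray, phi: np.ndarray,
) -> np.ndarray:
    """Directions on the dispersion cone about +-e1 (rows), sign-aligned
    with the previous direction, from pre-drawn variates: ``theta_std`` is
    standard-normal (scaled by sigma and folded to a half-normal polar
    angle), ``phi`` a uniform azimuth in [0, 2pi)."""
    theta = np.abs(theta_std) * np.deg2rad(sigma_deg)
    u, v = _orthonormal_frame(e1)
    perp = np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v
    d = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * perp
    flip = np.sum(d * previous, axis=-1) < 0.0
    d[flip] *= -1.0
    return d


def _sample_directions(
    e1: np.ndarray, sigma_deg: np.ndarray, previous: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Batched dispersion-cone sampling about +-e1 (rows). The polar angle
    is half-normal with scale sigma; the azimuth is uniform."""
    m = e1.shape[0]
    theta_std = rng.normal(0.0, 1.0, size=m)
    phi = rng.uniform(0.0, 2 * np.pi, size=m)
    return _directions_from_variates(e1, sigma_deg, previous, theta_std, phi)


def sample_direction(
    e1: np.ndarray,
    sigma_deg: float,
    previous_direction: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one propagation direction about +-``e1`` with spread
    ``sigma_deg``; of the two antipodal candidates the one continuing
    ``previous_direction`` is returned (``+e1`` hemisphere when no previous
    direction is given)."""
    e1 = np.asarray(e1, dtype=float)
    prev = e1 if previous_direction is None else np.asarray(previous_direction, dtype=float)
    return _sample_directions(e1[None, :], np.asarray([sigma_deg]), prev[None, :], rng)[0]


@dataclass
class Streamline:
    """One two-armed streamline: ordered world-mm points and the
    termination reason of each arm (negative arm first, positive second)."""

    points: np.ndarray
    reasons: tuple[str, str]


class _TensorField:
    """Trilinear samplers over a tensor volume and its FA map."""

    def __init__(self, tensors: TensorVolume, fa: ScalarVolume):
        require_aligned(tensors.grid, fa.grid, "tensor and FA volumes")
        self.grid = tensors.grid
        self.comp = np.ascontiguousarray(tensors.components)
        self.fa = np.ascontiguousarray(fa.values)

    def sample(self, vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """FA values and principal eigenvectors at continuous voxel coords."""
        fa = interpolate_volume(self.fa, vox)
        comp = np.stack([interpolate_volume(self.comp[..., c], vox) for c in range(6)], axis=-1)
        _, evecs = principal_directions(comp)
        return fa, evecs[..., 0, :]


def _propagate_arms(
    start_world: np.ndarray,
    init_prev: np.ndarray,
    field_: _TensorField,
    config: TrackingConfig,
    rng: np.random.Generator | list[np.random.Generator],
    groups: np.ndarray | None = None,
    label_values: np.ndarray | None = None,
    label_columns: np.ndarray | None = None,
    record_paths: bool = False,
) -> tuple[np.ndarray, list[str], list[list[np.ndarray]]]:
    """Advance a batch of arms until termination.

    ``rng`` may be one generator for the whole batch, or a list of
    per-group generators with ``groups`` assigning each arm to one of
    them; per step, each group draws exactly as many variates as it has
    arms still needing a direction, in ascending group order, so a group's
    random stream depends only on its own arms' fate.

    Returns per-arm target-hit matrix (M, T), termination reasons, and
    (when requested) the list of recorded points per arm.
    """
    grid = field_.grid
    step = config.resolved_step_mm(grid)
    cos_limit = np.cos(np.deg2rad(config.curvature_limit_deg))
    m = start_world.shape[0]
    if isinstance(rng, np.random.Generator):
        rngs = [rng]
        groups = np.zeros(m, dtype=int)
    else:
        rngs = list(rng)
        if groups is None or len(groups) != m:
            raise ValueError("per-group rngs require a groups array of length m")
        groups = np.asarray(groups, dtype=int)
    pos = start_world.astype(float).copy()
    prev = init_prev.astype(float).copy()
    active = np.ones(m, dtype=bool)
    reasons = np.full(m, -1, dtype=np.int8)
    n_targets = 0 if label_columns is None else int(label_columns.max(initial=-1)) + 1
    hits = np.zeros((m, max(n_targets, 1)), dtype=bool)
    paths: list[list[np.ndarray]] = [[p.copy()] for p in pos] if record_paths else []

    def look_up_labels(idx: np.ndarray, world: np.ndarray) -> None:
        if label_values is None or idx.size == 0:
            return
        vox = np.rint(grid.world_to_voxel(world)).astype(int)
        ok = np.all((vox >= 0) & (vox < np.asarray(grid.dims)), axis=-1)
        if not np.any(ok):
            return
        lab = label_values[tuple(vox[ok].T)]
        cols = label_columns[lab]
        keep = cols >= 0
        hits[idx[ok][keep], cols[keep]] = True

    look_up_labels(np.arange(m), pos)

    for _ in range(config.max_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        vox = grid.world_to_voxel(pos[idx])
        inside = grid.contains_voxel(vox) & np.all(
            (vox >= 0) & (vox <= np.asarray(grid.dims, dtype=float) - 1), axis=-1
        )
        out = idx[~inside]
        reasons[out] = _REASONS.index(TERM_LEFT_GRID)
        active[out] = False
        idx = idx[inside]
        if idx.size == 0:
            continue
        vox = vox[inside]

        fa, e1 = field_.sample(vox)
        low = fa < config.fa_floor
        stop = idx[low]
        reasons[stop] = _REASONS.index(TERM_FA_FLOOR)
        active[stop] = False
        idx = idx[~low]
        if idx.size == 0:
            continue
        fa, e1 = fa[~low], e1[~low]

        sigma = np.asarray(dispersion_from_fa(fa, config))
        theta_std = np.empty(idx.size)
        phi = np.empty(idx.size)
        gids = groups[idx]
        for g in np.unique(gids):  # ascending: draw order is deterministic
            sel = gids == g
            k = int(sel.sum())
            theta_std[sel] = rngs[g].normal(0.0, 1.0, size=k)
            phi[sel] = rngs[g].uniform(0.0, 2 * np.pi, size=k)
        d = _directions_from_variates(e1, sigma, prev[idx], theta_std, phi)
        bend = np.sum(d * prev[idx], axis=-1) < cos_limit - 1e-12
        kink = idx[bend]
        reasons[kink] = _REASONS.index(TERM_CURVATURE)
        active[kink] = False
        idx = idx[~bend]
        if idx.size == 0:
            continue
        d = d[~bend]

        pos[idx] = pos[idx] + step * d
        prev[idx] = d
        look_up_labels(idx, pos[idx])
        if record_paths:
            for i, p in zip(idx, pos[idx]):
                paths[i].append(p.copy())

    reasons[active] = _REASONS.index(TERM_MAX_STEPS)
    return hits, [_REASONS[r] for r in reasons], paths


def propagate_streamline(
    start_voxel: Sequence[int],
    tensors: TensorVolume,
    fa: ScalarVolume,
    config: TrackingConfig,
    rng: np.random.Generator | int | None = None,
) -> Streamline:
    """Propagate one streamline from a seed voxel centre.

    Two arms are launched along +e1 and -e1 of the tensor at the voxel
    centre; each advances by the configured step along freshly sampled
    directions until leaving the grid, dropping below the FA floor,
    exceeding the curvature limit, or hitting the step cap. The arms are
    concatenated (negative arm reversed) into one ordered point list.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.rng_seed if rng is None else int(rng))
    field_ = _TensorField(tensors, fa)
    grid = tensors.grid
    vox0 = np.asarray(start_voxel, dtype=float)
    if not np.all((vox0 >= 0) & (vox0 <= np.asarray(grid.dims) - 1)):
        raise ValueError(f"start voxel {start_voxel} outside the grid")
    fa0, e1 = field_.sample(vox0[None, :])
    if fa0[0] < config.fa_floor:
        raise ValueError(f"start voxel {start_voxel} has FA {fa0[0]:.3f} below the floor")
    start = grid.voxel_to_world(vox0)
    starts = np.stack([start, start])
    init = np.stack([-e1[0], e1[0]])
    _, reasons, paths = _propagate_arms(
        starts, init, field_, config, rng, record_paths=True
    )
    neg, pos = paths[0], paths[1]
    points = np.asarray(neg[::-1] + pos[1:])
    return Streamline(points=points, reasons=(reasons[0], reasons[1]))


@dataclass
class ConnectionProbabilityMap:
    """Per-seed-voxel connection probabilities to each target label."""

    grid: VolumeGrid
    seed_voxels: np.ndarray          # (K, 3) int, lexicographic order
    targets: list[int]               # ordered target labels
    target_names: list[str]
    probabilities: np.ndarray        # (K, T) in [0, 1]
    flagged: np.ndarray              # (K,) seeds skipped (FA below floor)
    config: TrackingConfig
    rng_seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (len(self.seed_voxels), len(self.targets)):
            raise ValueError("probabilities shape does not match seeds x targets")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.probabilities = p

    def to_volumes(self) -> np.ndarray:
        """Dense (dims + (T,)) probability array, zero outside the seed."""
        out = np.zeros(self.grid.dims + (len(self.targets),))
        idx = tuple(self.seed_voxels.T)
        for t in range(len(self.targets)):
            out[..., t][idx] = self.probabilities[:, t]
        return out

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.seed_voxels, columns=["i", "j", "k"])
        for t, name in enumerate(self.target_names):
            df[name] = self.probabilities[:, t]
        df["flagged"] = self.flagged.astype(int)
        return df


def estimate_connection_probabilities(
    seed_mask: MaskVolume,
    target_labels: LabelVolume,
    tensors: TensorVolume,
    fa: ScalarVolume,
    config: TrackingConfig,
) -> ConnectionProbabilityMap:
    """Monte Carlo seed-to-target connection probabilities.

    For each seed voxel, ``config.samples_per_seed`` two-armed streamlines
    are propagated; the probability for target t is the fraction of
    streamlines with at least one point in a voxel labeled t (any-visit
    rule; one streamline may count toward several targets). Seed voxels
    whose FA is already below the floor are flagged and get all-zero rows.
    """
    require_aligned(seed_mask.grid, tensors.grid, "seed mask and tensors")
    require_aligned(target_labels.grid, tensors.grid, "targets and tensors")
    if seed_mask.n_true == 0:
        raise ValueError("empty seed mask")
    targets = sorted(target_labels.label_table)
    if not targets:
        raise ValueError("target label volume names no targets")
    names = [target_labels.label_table[t] for t in targets]
    columns = np.full(max(targets) + 1, -1, dtype=int)
    for c, t in enumerate(targets):
        columns[t] = c

    field_ = _TensorField(tensors, fa)
    grid = tensors.grid
    seeds = seed_mask.voxel_indices()
    n = config.samples_per_seed
    probs = np.zeros((len(seeds), len(targets)))
    master = int(config.rng_seed) % (2**31)

    fa0, e1 = field_.sample(seeds.astype(float))
    flagged = fa0 < config.fa_floor
    ok = np.flatnonzero(~flagged)
    if ok.size:
        # one global batch: 2n arms per usable seed voxel, each voxel
        # driven by its own rng substream keyed on its position in the
        # lexicographic seed list
        rngs = [np.random.default_rng([master, int(i)]) for i in ok]
        centers = grid.voxel_to_world(seeds[ok].astype(float))
        starts = np.repeat(centers, 2 * n, axis=0)
        init = np.empty((ok.size, 2 * n, 3))
        init[:, 0::2] = -e1[ok][:, None, :]
        init[:, 1::2] = e1[ok][:, None, :]
        groups = np.repeat(np.arange(ok.size), 2 * n)
        hits, _, _ = _propagate_arms(
            starts, init.reshape(-1, 3), field_, config, rngs, groups=groups,
            label_values=target_labels.values, label_columns=columns,
        )
        hits = hits[:, : len(targets)].reshape(ok.size, 2 * n, len(targets))
        stream_hits = hits[:, 0::2] | hits[:, 1::2]
        probs[ok] = stream_hits.mean(axis=1)

    return ConnectionProbabilityMap(
        grid=grid,
        seed_voxels=seeds,
        targets=targets,
        target_names=names,
        probabilities=probs,
        flagged=flagged,
        config=replace(config),
        rng_seed=master,
    )
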