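"""Dispersion model, direction sampling, streamline propagation, Monte
Carlo connection probabilities and their lattice-toy oracle."""

import numpy as np
import pytest

import thalconn as tc
from thalconn.lattice import (
    lattice_connection_probability_exact,
    lattice_connection_probability_mc,
)
from thalconn.tracking import (
    TERM_CURVATURE,
    TERM_FA_FLOOR,
    TERM_LEFT_GRID,
    TERM_MAX_STEPS,
    dispersion_from_fa,
    sample_direction,
)
from thalconn.volumes import matrices_to_components


class TestDispersionFromFA:
    def test_boundaries_and_midpoint(self):
        cfg = tc.TrackingConfig(sigma_min_deg=2.0, sigma_max_deg=40.0)
        assert dispersion_from_fa(1.0, cfg) == 2.0
        assert dispersion_from_fa(0.0, cfg) == 40.0
        assert np.isclose(dispersion_from_fa(0.5, cfg), 21.0)

    def test_monotone_non_increasing(self):
        cfg = tc.TrackingConfig(sigma_min_deg=3.0, sigma_max_deg=30.0)
        fa = np.linspace(0, 1, 50)
        sigma = dispersion_from_fa(fa, cfg)
        assert np.all(np.diff(sigma) <= 1e-12)


class TestSampleDirection:
    def test_zero_dispersion_returns_e1_exactly(self):
        rng = np.random.default_rng(0)
        e1 = np.array([0.0, 0.0, 1.0])
        d = sample_direction(e1, 0.0, None, rng)
        assert np.allclose(d, e1, atol=1e-12)

    def test_hemisphere_continuity(self):
        rng = np.random.default_rng(0)
        e1 = np.array([1.0, 0.0, 0.0])
        d = sample_direction(e1, 0.0, -e1, rng)
        assert np.allclose(d, -e1, atol=1e-12)

    def test_unit_norm_and_mean_deviation(self):
        """10,000 draws at sigma=10 deg: mean angular deviation within 3
        standard errors of the half-normal mean sigma*sqrt(2/pi)."""
        rng = np.random.default_rng(123)
        e1 = np.array([0.0, 1.0, 0.0])
        sigma = 10.0
        n = 10_000
        angles = np.empty(n)
        for i in range(n):
            d = sample_direction(e1, sigma, None, rng)
            assert abs(np.linalg.norm(d) - 1.0) < 1e-9
            angles[i] = np.degrees(np.arccos(np.clip(abs(d @ e1), -1, 1)))
        mean_expected = sigma * np.sqrt(2 / np.pi)
        se = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(angles.mean() - mean_expected) < 3 * se


class TestPropagation:
    def test_straight_bundle_colinear_deterministic(self, bundle_phantom):
        """Zero dispersion on the straight bundle: points stay on the tube
        axis to 1e-6 and arms stop at the FA boundary or grid edge."""
        spec, tensors, _ = bundle_phantom
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(sigma_min_deg=0.0, sigma_max_deg=0.0, rng_seed=0)
        center = spec.bundles[0].seed_patch.voxel_indices().mean(axis=0).round().astype(int)
        sl = tc.propagate_streamline(center, tensors, fa, cfg)
        start_world = tensors.grid.voxel_to_world(center.astype(float))
        lateral = sl.points[:, [0, 2]] - start_world[[0, 2]]
        assert np.max(np.abs(lateral)) < 1e-6
        assert len(sl.points) > 5
        assert set(sl.reasons) <= {TERM_FA_FLOOR, TERM_LEFT_GRID}

    def test_seed_below_fa_floor_signalled(self):
        grid = tc.VolumeGrid.isotropic((6, 6, 6), 2.0)
        comp = np.zeros(grid.dims + (6,))
        comp[..., 0] = comp[..., 3] = comp[..., 5] = 1e-3  # isotropic
        tensors = tc.TensorVolume(grid, comp)
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(fa_floor=0.1)
        with pytest.raises(ValueError, match="below the floor"):
            tc.propagate_streamline((3, 3, 3), tensors, fa, cfg)

    def test_sharp_bend_terminates_on_curvature(self):
        """A 90-degree direction-field bend crossed in one step exceeds a
        45-degree curvature limit."""
        grid = tc.VolumeGrid.isotropic((9, 21, 9), 1.0)
        along_y = matrices_to_components(np.diag([0.3e-3, 1.7e-3, 0.3e-3]))
        along_x = matrices_to_components(np.diag([1.7e-3, 0.3e-3, 0.3e-3]))
        comp = np.tile(along_y, grid.dims + (1,))
        comp[:, 12:, :, :] = along_x
        tensors = tc.TensorVolume(grid, comp)
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(step_mm=2.0, curvature_limit_deg=45.0,
                                sigma_min_deg=0.0, sigma_max_deg=0.0)
        sl = tc.propagate_streamline((4, 4, 4), tensors, fa, cfg)
        assert TERM_CURVATURE in sl.reasons

    def test_max_steps_hard_bound(self, bundle_phantom):
        _, tensors, _ = bundle_phantom
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(max_steps=5, sigma_min_deg=0.0, sigma_max_deg=0.0)
        spec = bundle_phantom[0]
        center = spec.bundles[0].seed_patch.voxel_indices().mean(axis=0).round().astype(int)
        sl = tc.propagate_streamline(center, tensors, fa, cfg)
        assert len(sl.points) <= 2 * cfg.max_steps + 1
        assert TERM_MAX_STEPS in sl.reasons


class TestConnectionProbabilities:
    def test_zero_dispersion_deterministic_connection(self, bundle_phantom):
        """Every seed-patch voxel connects with probability exactly 1."""
        spec, tensors, truth = bundle_phantom
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(sigma_min_deg=0.0, sigma_max_deg=0.0,
                                samples_per_seed=8, rng_seed=0)
        cpm = tc.estimate_connection_probabilities(
            spec.seed_region, spec.targets, tensors, fa, cfg)
        in_patch = truth.values[tuple(cpm.seed_voxels.T)] == 1
        assert in_patch.sum() == spec.bundles[0].seed_patch.n_true
        assert np.all(cpm.probabilities[in_patch, 0] == 1.0)
        assert np.all(cpm.probabilities[~in_patch, 0] == 0.0)

    def test_isotropic_seed_voxels_flagged_zero(self, bundle_phantom):
        spec, tensors, truth = bundle_phantom
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(samples_per_seed=4, rng_seed=0)
        cpm = tc.estimate_connection_probabilities(
            spec.seed_region, spec.targets, tensors, fa, cfg)
        background = truth.values[tuple(cpm.seed_voxels.T)] == 0
        assert np.all(cpm.flagged[background])
        assert np.all(cpm.probabilities[background] == 0.0)

    def test_determinism_same_seed(self, bundle_phantom):
        spec, tensors, _ = bundle_phantom
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(samples_per_seed=20, rng_seed=77)
        a = tc.estimate_connection_probabilities(spec.seed_region, spec.targets, tensors, fa, cfg)
        b = tc.estimate_connection_probabilities(spec.seed_region, spec.targets, tensors, fa, cfg)
        assert np.array_equal(a.probabilities, b.probabilities)
        c = tc.estimate_connection_probabilities(
            spec.seed_region, spec.targets, tensors, fa,
            tc.TrackingConfig(samples_per_seed=20, rng_seed=78))
        assert not np.array_equal(a.probabilities, c.probabilities)

    def test_target_superset_monotonicity(self, bundle_phantom):
        """Enlarging the target region never lowers its probability at
        fixed seed."""
        spec, tensors, _ = bundle_phantom
        fa = tc.compute_fa(tensors)
        cfg = tc.TrackingConfig(samples_per_seed=50, rng_seed=5)
        small = tc.estimate_connection_probabilities(
            spec.seed_region, spec.targets, tensors, fa, cfg)
        grown = spec.targets.values.copy()
        grown[:, -8:, :] = 1  # superset of target 1
        big_targets = tc.LabelVolume(spec.grid, grown, spec.targets.label_table)
        big = tc.estimate_connection_probabilities(
            spec.seed_region, big_targets, tensors, fa, cfg)
        assert np.all(big.probabilities[:, 0] >= small.probabilities[:, 0])

    def test_empty_seed_rejected(self, bundle_phantom):
        spec, tensors, _ = bundle_phantom
        fa = tc.compute_fa(tensors)
        empty = tc.MaskVolume(spec.grid, np.zeros(spec.grid.dims, bool))
        with pytest.raises(ValueError, match="empty seed"):
            tc.estimate_connection_probabilities(
                empty, spec.targets, tensors, fa, tc.TrackingConfig())


class TestLatticeToy:
    def test_exact_probability_simple_cases(self):
        # target on every path -> 1; unreachable target -> 0
        assert lattice_connection_probability_exact(0.5, 4, {(0, 0)}) == 1.0
        assert lattice_connection_probability_exact(0.5, 4, {(1, 2)}) == 0.0  # parity
        # single-step: right cell visited with probability p
        assert np.isclose(lattice_connection_probability_exact(0.3, 1, {(1, 1)}), 0.3)

    def test_mc_matches_exact_within_binomial_error(self):
        rng_seed = 2024
        configs = [
            (0.5, 10, {(0, 10)}),
            (0.3, 8, {(2, 8), (4, 8)}),
            (0.7, 12, {(1, 5)}),
        ]
        n = 20_000
        for p_right, steps, targets in configs:
            p = lattice_connection_probability_exact(p_right, steps, targets)
            est = lattice_connection_probability_mc(p_right, steps, targets, n, rng_seed)
            assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n) + 1e-12

    def test_mc_error_scales_inverse_sqrt_n(self):
        """Standard error of the estimate shrinks like 1/sqrt(N)."""
        p_right, steps, targets = 0.5, 10, {(2, 6)}
        p = lattice_connection_probability_exact(p_right, steps, targets)
        for n in (1_000, 10_000, 100_000):
            errs = [
                abs(lattice_connection_probability_mc(p_right, steps, targets, n, seed) - p)
                for seed in range(8)
            ]
            # RMS error within a factor ~2 of the binomial prediction
            rms = np.sqrt(np.mean(np.square(errs)))
            assert rms < 2.0 * np.sqrt(p * (1 - p) / n)
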