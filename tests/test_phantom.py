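"""Phantom construction, DWI synthesis, cohort generation, lesion masks."""

import numpy as np
import pytest

import thalconn as tc
from thalconn.dti import fa_from_eigenvalues

from conftest import single_bundle_spec


class TestTensorPhantom:
    def test_straight_bundle_eigenvector_and_fa(self, bundle_phantom):
        """In-tube voxels carry e1=(0,1,0) and the closed-form FA of
        eigenvalues (1.7, 0.3, 0.3)e-3."""
        spec, tensors, _ = bundle_phantom
        fa = tc.compute_fa(tensors)
        expected_fa = fa_from_eigenvalues((1.7e-3, 0.3e-3, 0.3e-3))
        patch = spec.bundles[0].seed_patch.values
        assert patch.sum() > 0
        for vox in np.argwhere(patch):
            es = tc.eigendecompose(tensors.components[tuple(vox)])
            assert abs(abs(es.e1 @ np.array([0.0, 1.0, 0.0])) - 1.0) < 1e-9
            assert abs(fa.values[tuple(vox)] - expected_fa) < 1e-12

    def test_no_bundles_is_uniformly_isotropic(self):
        grid = tc.VolumeGrid.isotropic((8, 8, 8), 2.0)
        empty_mask = np.zeros(grid.dims, dtype=bool)
        empty_mask[4, 4, 4] = True
        spec = tc.PhantomSpec(
            grid=grid,
            bundles=[],
            seed_region=tc.MaskVolume(grid, empty_mask),
            targets=tc.LabelVolume(grid, np.zeros(grid.dims, dtype=np.int32), {}),
        )
        tensors, truth = tc.build_tensor_phantom(spec)
        assert np.all(tc.compute_fa(tensors).values == 0.0)
        assert np.all(truth.values == 0)

    def test_ground_truth_partitions_seed_patches(self, default_phantom):
        spec, _, truth = default_phantom
        for bundle in spec.bundles:
            labels = np.unique(truth.values[bundle.seed_patch.values])
            assert labels.tolist() == [bundle.target_label]
        # patches are disjoint and jointly cover all nonzero truth
        total = sum(b.seed_patch.n_true for b in spec.bundles)
        assert total == int(np.sum(truth.values > 0))

    def test_in_bundle_eigenvector_tracks_tangent(self):
        """Curved-bundle tangents: |dot(tangent, e1)| > 0.999 in-tube."""
        grid = tc.VolumeGrid.isotropic((24, 24, 8), 2.0)
        # quarter-circle bundle in the xy plane
        t = np.linspace(0, np.pi / 2, 12)
        radius = 30.0
        line = np.stack([radius * np.sin(t) + 4, radius * (1 - np.cos(t)) + 4, 7 * np.ones_like(t) ], axis=1)
        patch = np.zeros(grid.dims, dtype=bool)
        patch[2, 2, 3] = True
        spec = tc.PhantomSpec(
            grid=grid,
            bundles=[tc.BundleSpec("arc", line, 3.0, tc.MaskVolume(grid, patch), 1)],
            seed_region=tc.MaskVolume(grid, patch),
            targets=tc.LabelVolume(grid, np.zeros(grid.dims, np.int32), {}),
        )
        tensors, _ = tc.build_tensor_phantom(spec)
        fa = tc.compute_fa(tensors)
        in_tube = np.argwhere(fa.values > 0.5)
        assert len(in_tube) > 20
        center = np.array([4.0, 4.0 + radius])  # circle centre in the xy plane
        checked = 0
        for vox in in_tube:
            world = grid.voxel_to_world(vox.astype(float))
            rel = world[:2] - center
            theta = np.arctan2(rel[0], -rel[1])  # 0 at arc start, pi/2 at end
            if not (0.15 < theta < np.pi / 2 - 0.15):
                continue  # skip tube end caps, where the tangent is clamped
            checked += 1
            es = tc.eigendecompose(tensors.components[tuple(vox)])
            radial = rel / np.linalg.norm(rel)
            tangent = np.array([-radial[1], radial[0], 0.0])
            assert abs(np.dot(es.e1, tangent)) > 0.999
            assert abs(np.linalg.norm(es.e1) - 1.0) < 1e-9
        assert checked > 15


class TestSynthesizeDwi:
    def test_isotropic_closed_form_signal(self, small_protocol):
        grid = tc.VolumeGrid.isotropic((2, 2, 2), 2.0)
        d = 1.1e-3
        comp = np.zeros(grid.dims + (6,))
        comp[..., 0] = comp[..., 3] = comp[..., 5] = d
        dwi = tc.synthesize_dwi(tc.TensorVolume(grid, comp), small_protocol, s0=500.0)
        weighted = small_protocol.bvalues > 0
        expected = 500.0 * np.exp(-small_protocol.bvalues[weighted] * d)
        assert np.allclose(dwi.data[0, 0, 0][weighted], expected)

    def test_b0_frames_equal_s0(self, small_protocol, bundle_phantom):
        _, tensors, _ = bundle_phantom
        dwi = tc.synthesize_dwi(tensors, small_protocol, s0=800.0)
        assert np.allclose(dwi.data[..., small_protocol.b0_mask], 800.0)

    def test_noise_reproducible_and_rician(self, small_protocol, bundle_phantom):
        _, tensors, _ = bundle_phantom
        a = tc.synthesize_dwi(tensors, small_protocol, snr_b0=10.0, rng_seed=3)
        b = tc.synthesize_dwi(tensors, small_protocol, snr_b0=10.0, rng_seed=3)
        c = tc.synthesize_dwi(tensors, small_protocol, snr_b0=10.0, rng_seed=4)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        assert np.all(a.data >= 0)  # magnitude reconstruction

    def test_invalid_parameters(self, small_protocol, bundle_phantom):
        _, tensors, _ = bundle_phantom
        with pytest.raises(ValueError):
            tc.synthesize_dwi(tensors, small_protocol, s0=-1.0)
        with pytest.raises(ValueError):
            tc.synthesize_dwi(tensors, small_protocol, snr_b0=0.0)


class TestCohort:
    def test_no_jitter_no_noise_reproduces_phantom(self, small_protocol):
        spec = single_bundle_spec(dims=(14, 20, 14))
        tensors, _ = tc.build_tensor_phantom(spec)
        cohort = tc.CohortSpec(n_subjects=2, snr_b0=np.inf, rotation_max_deg=0.0,
                               translation_max_mm=0.0, rng_seed=1)
        subjects = tc.generate_cohort(spec, cohort, small_protocol)
        reference = tc.synthesize_dwi(tensors, small_protocol)
        for dwi, transform in subjects:
            assert np.allclose(dwi.data, reference.data, rtol=1e-10)
            assert np.allclose(transform.matrix, np.eye(4))

    def test_same_seed_bit_identical(self, small_protocol):
        spec = single_bundle_spec(dims=(14, 20, 14))
        cohort = tc.CohortSpec(n_subjects=2, snr_b0=15.0, rng_seed=9)
        a = tc.generate_cohort(spec, cohort, small_protocol)
        b = tc.generate_cohort(spec, cohort, small_protocol)
        for (da, ta), (db, tb) in zip(a, b):
            assert np.array_equal(da.data, db.data)
            assert np.array_equal(ta.matrix, tb.matrix)

    def test_cohort_size_nineteen(self, small_protocol):
        spec = single_bundle_spec(dims=(14, 20, 14))
        cohort = tc.CohortSpec(n_subjects=19, snr_b0=np.inf, rotation_max_deg=0.5,
                               translation_max_mm=0.5, rng_seed=2)
        subjects = tc.generate_cohort(spec, cohort, small_protocol)
        assert len(subjects) == 19

    def test_excessive_jitter_rejected(self, small_protocol):
        spec = single_bundle_spec(dims=(14, 20, 14))
        cohort = tc.CohortSpec(n_subjects=1, snr_b0=np.inf, rotation_max_deg=0.0,
                               translation_max_mm=40.0, rng_seed=0)
        with pytest.raises(ValueError, match="off the grid"):
            tc.generate_cohort(spec, cohort, small_protocol)


class TestLesionMask:
    def test_sphere_volume_matches_analytic(self):
        # r = 5.26 mm sphere on a 1 mm grid: volume within 10% of (4/3) pi r^3
        grid = tc.VolumeGrid.isotropic((20, 20, 20), 1.0)
        lesion = tc.LesionSpec(center_mm=(9.5, 9.5, 9.5), semi_axes_mm=(5.26, 5.26, 5.26))
        mask = tc.generate_lesion_mask(lesion, grid)
        analytic = 4.0 / 3.0 * np.pi * 5.26**3
        assert abs(mask.volume_mm3 - analytic) / analytic < 0.10

    def test_sub_voxel_lesion_between_centres_errors(self):
        grid = tc.VolumeGrid.isotropic((10, 10, 10), 1.0)
        lesion = tc.LesionSpec(center_mm=(4.5, 4.5, 4.5), semi_axes_mm=(0.4, 0.4, 0.4))
        with pytest.raises(ValueError, match="no voxel centres"):
            tc.generate_lesion_mask(lesion, grid)

    def test_volume_equals_brute_force_count(self):
        grid = tc.VolumeGrid.isotropic((16, 16, 16), 1.3)
        rng = np.random.default_rng(5)
        for _ in range(5):
            center = rng.uniform(5, 15, size=3)
            axes = rng.uniform(2.0, 6.0, size=3)
            mask = tc.generate_lesion_mask(tc.LesionSpec(tuple(center), tuple(axes)), grid)
            count = 0
            for vox in np.ndindex(grid.dims):
                rel = (grid.voxel_to_world(np.asarray(vox, float)) - center) / axes
                count += np.sum(rel**2) <= 1.0
            assert mask.n_true == count
            assert np.isclose(mask.volume_mm3, count * grid.voxel_volume_mm3)
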