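# Methods

`thalconn` implements connectivity-based parcellation of a subcortical seed
structure (the motivating case is the human thalamus) from diffusion-tensor
imaging, together with lesion-overlap reporting against the resulting
segmentation. This note documents the models, the synthetic data they are
validated on, the numerical choices, and the limits of what the validation
shows.

## Pipeline model

**Diffusion tensor.** Water diffusion per voxel is modeled as a single
3×3 symmetric positive semi-definite tensor `D` (mm²/s) under the
mono-exponential signal model `S(b, g) = S0 · exp(−b gᵀ D g)`. Tensors are
estimated by unweighted log-linear least squares on `ln S`: a single
pseudo-inverse of the (frames × 7) design matrix applied to all voxels at
once. The fit is deterministic and, on noiseless synthetic data, recovers
the generating tensor to machine precision — which is what makes it usable
as its own oracle in round-trip tests. Weighted or nonlinear (positivity
constrained) estimators would be statistically better at low SNR but are
deliberately out of scope; negative eigenvalues arising under noise are
clipped to zero (eigenvectors kept) and the voxel is flagged in a QC map.

**Fractional anisotropy.** `FA = sqrt(3/2) · ‖D − (tr D/3) I‖_F / ‖D‖_F`,
clipped to [0, 1], with `FA = 0` assigned to the zero tensor by convention.
Because FA is scale invariant, tensors with Frobenius norm below
1e−12 mm²/s (roundoff from constant-signal fits; physical diffusivities
are ~1e−3) are treated as zero rather than given an arbitrary FA.

**Group template.** Subject tensor volumes are resampled onto the template
grid through affine world→world transforms: each output voxel centre is
pulled back through the inverse transform, the six tensor components are
interpolated trilinearly, and the interpolated tensor is reoriented with
the Preservation of Principal Direction (PPD) rule using the transform's
linear part `F`:

    n1 = F e1 / ‖F e1‖,   n2 = normalize(F e2 − (F e2 · n1) n1),
    n3 = n1 × n2,         D′ = Σᵢ λᵢ nᵢ nᵢᵀ.

PPD preserves eigenvalues exactly and reduces to conjugation `R D Rᵀ` for
pure rotations — both properties are asserted as oracles. Only affine
transforms are implemented: estimating nonlinear registrations is the job
of external tools, and a constant Jacobian makes PPD exact per volume. The
template is the arithmetic per-component mean across subjects (Euclidean,
not log-Euclidean), restricted per voxel to the subjects whose field of
view covers it; a coverage-count map is emitted alongside. Euclidean
averaging is known to be swelling-prone relative to log-Euclidean
statistics, but it is the convention this pipeline standardises on, and
the choice is testable (linearity, idempotence).

**Probabilistic tractography.** Connection probabilities are estimated by
Monte Carlo streamline propagation in the PICo spirit: direction
uncertainty per step reflects the local confidence in the principal
eigenvector. From each seed voxel, `N` streamlines are launched as two
arms along ±e1 of the tensor at the voxel centre. Each step:

1. the tensor and FA are interpolated trilinearly at the current point
   (eigendecomposition after interpolation);
2. an angular dispersion σ(FA) is computed — linear from `sigma_max_deg`
   at FA = 0 to `sigma_min_deg` at FA = 1, monotone non-increasing because
   lower anisotropy means a less reliable direction estimate;
3. a direction is drawn from an axially symmetric cone about ±e1: polar
   angle half-normal with scale σ, azimuth uniform, antipode chosen to
   continue the previous direction;
4. the arm advances by `step_mm`, or terminates on leaving the grid,
   FA below `fa_floor`, a per-step turn above `curvature_limit_deg`, or
   `max_steps`.

The probability of connection of a seed voxel to target `t` is the
fraction of its `N` streamlines with at least one point whose
nearest voxel carries label `t` (any-visit rule; a streamline may count
toward several targets). The calibrated lookup-table PDFs of the original
PICo implementations are not reproduced; the linear FA→σ map preserves the
operative principle while remaining analytically checkable (σ = 0 makes
propagation fully deterministic, which several tests exploit).

**Parcellation.** Each seed voxel is labeled with its maximum-probability
target (winner take all). Voxels whose *maximum* probability falls below
`min_probability` (default 0.5) are discarded to label 0 — the threshold
applies to the winning probability, not per target — because such voxels
are more plausibly connected to regions outside the target set. Ties break
to the earliest target in the configured order and are counted in the
result's provenance. Probabilities are used raw (not renormalised across
targets) before the arg-max. The seed mask itself is built by binarizing a
probabilistic atlas volume at an inclusive threshold (default 0.25), with
percent-vs-unit scale auto-detected (any value > 1 ⇒ percent).

**Lesion overlap.** Lesion masks are resampled to the template grid by
nearest-neighbour pull-back (preserving binarity), then intersected with
the parcellation. For each target, the report gives
`100 · |lesion ∩ label_t| / |lesion|`; the denominator is the whole
lesion, including voxels outside the seed structure, so per-target rows
need not sum to 100 on their own — the unassigned share closes the budget
to exactly 100. TSV output prints one decimal place; a JSON sidecar keeps
full precision.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `step_mm` | max(1.0, half min voxel) | mm | 1 mm on a 1 mm template grid, half a voxel on coarser acquisition grids |
| `max_steps` | 2000 | steps/arm | hard termination bound; generous for brain-scale distances |
| `curvature_limit_deg` | 80 | deg/step | rejects near-reversals while allowing curved bundles |
| `fa_floor` | 0.1 | — | stops propagation in effectively isotropic tissue |
| `samples_per_seed` | 1000 | streamlines | binomial SE ≤ 0.016 per probability |
| `sigma_min_deg`, `sigma_max_deg` | 2, 40 | deg | dispersion at FA = 1 and FA = 0 |
| seed-atlas threshold | 0.25 | probability | conventional atlas binarisation level |
| `min_probability` | 0.5 | probability | discard rule for weakly connected seed voxels |
| bundle diffusivities | 1.7e−3 / 0.3e−3 | mm²/s | typical healthy white matter axial/radial values (FA ≈ 0.80) |
| background diffusivity | 0.8e−3 | mm²/s | gray-matter-like isotropic tissue |
| `snr_b0` | 20 | — | typical b=0 SNR of a 3T diffusion acquisition |
| cohort size | 19 | subjects | the healthy-control cohort size the analysis assumes |

## Synthetic data: what it emulates, and what it does not

The phantom generator produces the statistical structure the analysis
assumes, with known ground truth:

- **Geometry.** Fiber bundles are tubes of configurable radius around
  piecewise-cubic, arc-length-resampled centerlines; inside a tube the
  tensor is axially symmetric with e1 along the local tangent, outside it
  is isotropic. The default study phantom is a 40×60×40 grid at 2.3 mm
  isotropic (a typical DWI acquisition resolution; a 1 mm option mirrors
  template resolution) with three parallel bundles joining three seed
  patches to three disjoint target blocks named BA6/BA9/BA32. Each
  bundle's seed patch is exactly the tube cross-section inside the seed
  slab, so the ground-truth labeling coincides with what the bundle
  actually connects — with zero noise and zero dispersion the pipeline
  must (and does) reproduce it voxel for voxel.
- **Signal.** DWI frames follow the tensor model with Rician noise
  (`sqrt((S+n1)² + n2²)`, iid Gaussian n1, n2 of scale `s0/snr_b0`),
  matching magnitude-MRI statistics. The default protocol is 9 b=0 frames
  plus 81 unique directions at b = 1000 s/mm² on a spherical Fibonacci
  hemisphere.
- **Cohort.** Subjects are the phantom resampled under small random rigid
  transforms (rotation ≤ 2°, translation ≤ 2 mm by default) with PPD
  reorientation and independent noise; the recorded inverse transform
  plays the role of a subject→template registration. All generators are
  pure functions of their specs and an integer seed.
- **Lesions.** Axis-aligned ellipsoids rasterised by voxel-centre
  inclusion, with volumes in the few-hundred-mm³ range of real lacunar
  thalamic infarcts.

Features of real data that are *not* emulated — and that passing tests
therefore say nothing about: crossing/branching fibers (single-tensor
phantoms by construction; where tubes overlap, the last-listed bundle
wins and the overlap is logged), nonlinear anatomical variability (only
rigid jitter; registration estimation is out of scope), eddy-current and
susceptibility distortion, partial-volume and CSF contamination, and the
distance-dependent attenuation of connection probability over realistic
cortico-subcortical path lengths (phantom bundles are short and straight).

## Numerical choices

- **Signal floor.** Signals are clamped to `1e−6 ×` the mean b=0 signal
  before the log transform; clamped voxels are flagged.
- **Eigendecomposition.** `numpy.linalg.eigh` with descending eigenvalue
  order and a deterministic sign convention (each eigenvector's
  largest-magnitude component positive), so repeated runs decompose
  identically. Degenerate eigenvalues yield an arbitrary but orthonormal
  basis; tolerance on negative-eigenvalue clipping is 1e−15 so roundoff
  does not raise QC flags.
- **Reproducibility of tractography.** One master seed; seed voxel `i`
  (in lexicographic order) draws from `default_rng([master_seed, i])`.
  All arms propagate in one global batch for speed, but each voxel's
  substream advances only by its own arms' draws, so results are
  independent of batching and processing order. Identical config + seed
  ⇒ bit-identical probability maps, and the end-to-end driver writes
  byte-identical `report.json` across reruns.
- **Grid alignment.** Cross-volume operations require equal dims and
  affines agreeing element-wise to 1e−4, or an explicit transform.
- **Interpolation.** Trilinear for tensors/FA (component-wise, then
  eigendecomposition), nearest-neighbour for labels and masks. Points
  outside the grid read as zero and terminate propagation.
- **Tie-breaks.** Winner-take-all ties go to the first target in the
  configured order; the tie count is reported.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to run on
a single CPU in minutes: the full-noise parcellation check uses the
default 40×60×40 phantom at SNR 20 with N = 1000 samples per seed voxel
(~1300 seed voxels, of which ~370 exceed the FA floor); the template check
averages 19 subjects on a 16×24×16 single-bundle phantom; the end-to-end
determinism check runs the whole pipeline twice on a 32×48×32 phantom
with 3 subjects and N = 150. The Monte Carlo tractography estimator is
validated against exhaustive path enumeration on a two-choice lattice toy
(≤ 2¹⁴ paths) rather than against a second streamline implementation, so
the oracle is independent of the code path it checks.

## Known limitations

- Single-tensor diffusion model throughout: no crossing-fiber support in
  either the phantom or the tracker.
- Euclidean tensor averaging and affine-only warping, as discussed above.
- The FA→dispersion map is a modeling stand-in for calibrated PICo PDFs;
  absolute probability values depend on it and on the any-visit hit rule,
  so they are comparable within a configuration, not across tools.
- Connection probability decreases with seed–target distance (longer
  paths accumulate more chances to terminate or disperse), so distant
  targets are systematically disadvantaged — a property inherent to the
  method, not corrected for here.
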