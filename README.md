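# thalconn

Connectivity-based parcellation of subcortical seed structures from
diffusion-tensor MRI, and lesion-disconnection reports against the
resulting segmentation.

## The problem

Focal lesions of integrative structures such as the thalamus produce
cognitive deficits that are best explained not by the lesion's location
alone but by *which remote connections it interrupts*. Because diffusion
tractography is unreliable inside a lesion (anisotropy drops, so the
estimated fiber direction is untrustworthy), a practical strategy is to
map connectivity in healthy tissue first and then superimpose a patient's
lesion on that map: build a group-averaged diffusion-tensor template from
healthy controls, segment the seed structure by which cortical target
each voxel most probably connects to, and report what fraction of the
lesion falls in each connectivity-defined subregion.

`thalconn` implements that pipeline end to end, for volumes in NIfTI
format, together with a synthetic-phantom generator that provides ground
truth for every stage:

1. **Tensor fitting** — voxel-wise log-linear least squares on
   `ln S = ln S₀ − b gᵀ D g`, with FA maps
   `FA = √(3/2)·‖D − (tr D/3)I‖_F / ‖D‖_F`.
2. **Template building** — affine warping of tensor volumes with
   Preservation of Principal Direction (PPD) reorientation, then
   component-wise averaging across subjects.
3. **Probabilistic tractography** — Monte Carlo streamlines whose
   per-step direction is drawn from a dispersion cone around the local
   principal eigenvector e₁, wider where FA is lower; the probability of
   connection from a seed voxel to a target is the fraction of its N
   streamlines that visit the target's label.
4. **Winner-take-all parcellation** — each seed voxel takes the arg-max
   target of its probability vector; voxels whose winning probability is
   below 0.5 are discarded as likely connected elsewhere. The seed mask
   itself comes from binarizing a probabilistic atlas at 25%.
5. **Lesion overlap** — per lesion, the percent of voxels carrying each
   target label (denominator: the whole lesion), printed to one decimal
   as a TSV table plus a full-precision JSON sidecar.

## Worked example

Build the default three-bundle phantom (three seed patches connected to
targets named BA6, BA9, BA32), synthesize a noisy acquisition, and run
the pipeline:

```python
import thalconn as tc

spec = tc.default_phantom_spec(dims=(32, 48, 32))
tensors, truth = tc.build_tensor_phantom(spec)
protocol = tc.make_protocol(81, 9, 1000.0)   # 81 directions at b=1000 + 9 b=0
dwi = tc.synthesize_dwi(tensors, protocol, snr_b0=20.0, rng_seed=0)
fit = tc.fit_tensor_lls(dwi, protocol)
fa = tc.compute_fa(fit)

config = tc.TrackingConfig(samples_per_seed=500, rng_seed=0)
cpm = tc.estimate_connection_probabilities(
    spec.seed_region, spec.targets, fit, fa, config)
parc = tc.classify_winner_take_all(cpm, min_probability=0.5)
print("Dice vs ground truth:", tc.parcellation_dice(parc, truth))

lesions = [
    ("RF/LH", (18.0, 25.0, 36.0), (5.3, 5.3, 5.3)),   # inside the BA6 patch
    ("GP/RH", (62.0, 25.0, 36.0), (4.4, 4.4, 4.4)),   # off-bundle control
]
reports = []
for name, center, axes in lesions:
    mask = tc.generate_lesion_mask(tc.LesionSpec(center, axes), spec.grid)
    reports.append(tc.compute_overlap_report(mask, parc, name))
print(tc.format_report_tsv(reports))
```

Output:

```
Dice vs ground truth: {1: 1.0, 2: 1.0, 3: 1.0}
lesion_id	lesion_volume_mm3	BA6_percent	BA9_percent	BA32_percent	unassigned_percent
RF/LH	632.7	96.2	0.0	0.0	3.8
GP/RH	328.5	0.0	0.0	0.0	100.0
```

The parcellation recovers the ground-truth seed labeling perfectly
(Dice 1.0 per target) despite SNR-20 Rician noise. The first lesion — an
ellipsoid of 632.7 mm³ placed inside the BA6-connected patch — overlaps
that subregion in 96.2% of its voxels; the control lesion sits in tissue
with no strong prefrontal connection, so 100% of it is unassigned. That
contrast is exactly the kind of evidence the method produces for real
patients: two lesions of similar size can imply very different
disconnection patterns.

The same stages are available from the shell via the `thalconn` CLI
(`simulate`, `fit`, `template`, `tract`, `parcellate`, `overlap`,
`lesion`, and `run-all`, which chains everything from one YAML config and
one master seed).

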