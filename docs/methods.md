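# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of `petguard`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The prediction pipeline

A whole-body FDG-PET study is represented as a nonnegative SUV volume on a
`(z, y, x)` grid (z craniocaudal, slice 0 at the head; spacing in mm).
For each configured view azimuth θ the volume is rotated about z
(counterclockwise viewed from superior, trilinear interpolation,
out-of-field samples contribute 0) and the per-ray maximum along the
anterior-posterior axis is taken.  At axis-aligned angles on square grids
the rotation degenerates to an exact permutation, which the test suite
exploits for exact brute-force oracles.  The projection is windowed to
SUV 0–10 (`gray = clip(SUV/10, 0, 1)`) and resampled to 64 × 64 by linear
interpolation, letterboxing with zeros to preserve the physical aspect
ratio rather than stretching anisotropically.  Windowing precedes
resampling.  View schedules are uniform 10° steps: 0–180° inclusive for a
scanner-1 style acquisition (19 views) and 0–350° for scanner 2
(36 views) — the only uniform schedules producing those two counts at a
common step; both remain configurable per `ScannerProfile`.

The classifier is deliberately small: four 3 × 3 convolution blocks
(default 4/8/8/16 filters, He initialization), ReLU, local response
normalization after the first block (radius 2, α = 10⁻⁴, β = 0.75,
bias 1), 2 × 2 max pooling after blocks 1, 2 and 4 (64 → 32 → 16 → 8 px),
a 32-unit dense layer with dropout 0.5, and a softmax (sex) or linear
(age/weight) head.  The input images are coarse and the planted signal is
regional, so narrow layers suffice and keep single-CPU training fast;
widths, LRN placement and pooling positions are all `NetworkSpec` fields.
The engine is pure NumPy (convolution as one SGEMM over a patch matrix
assembled with nine slice copies); all arithmetic is float32 and fully
deterministic given the seeds, so repeated runs are bit-identical.

Training: Adam (lr 10⁻³, β = 0.9/0.999), batch 128, cross-entropy for sex
and mean-squared error on internally standardized targets for age/weight
(predictions are returned in years/kg).  A patient-level validation fold
(15 % of training patients) is carved out *before* augmentation; the
remaining training images are expanded 5-fold (original + 4 randomized
variants: rotation ≤ 10°, scale 0.9–1.1, translation ≤ 4 px, Gaussian
noise σ = 0.02 gray).  Validation and test images never pass through the
augmentation stage.  Early stopping monitors validation loss and stops
after `patience` (default 3) non-improving epochs; with `restore_best`
the returned weights are the best-epoch weights.

Aggregation: each view casts a hard sex vote (argmax probability); the
patient label is the modal vote.  Ties, possible only for even view
counts, are broken by the larger mean class probability and flagged
low-confidence (19 views cannot tie).  Age and weight aggregate by the
median across views — robust to an occasional degenerate view.  Alerts
compare the aggregate against claimed demographics: sex exact, age within
± 10 years, weight within ± 6 kg by default (configurable); these bands
mirror the accuracy the regressors themselves achieve.  A missing claimed
field yields an explicit "unverifiable" status, never a silent pass.
Confusion matrices use 18 age bins (0–10, 11–15, …, 86–90, ≥ 91 years;
ages in (10, 11) resolve downward: anything below 11 falls in the first
bin) and 14 weight bins (0–30, 31–35, …, 86–90, ≥ 91 kg).

## The synthetic cohort

The phantom is a stack of elliptical cross-sections in millimetre
coordinates (head, chest, abdomen, pelvis at fractional craniocaudal
bands 0–0.15 / 0.15–0.40 / 0.40–0.60 / 0.60–0.85; two thigh columns
below), covering head to mid-thigh (960 mm).  It is a statistical
stand-in, not an anatomical model; what matters is where the demographic
information lives:

* **Sex (pelvis, strong, low variance).**  Women receive a broad
  uterine/adnexal ellipsoid, men a broad gonadal/gluteal slab in the lower
  pelvic band.  Both features are scaled so that the noise-free mean SUV
  over pelvic-band body voxels is soft tissue + 0.30 for women and exactly
  1.5 SUV higher for men (`pelvis_sex_amplitude`).  Because the age drift
  of soft tissue spans at most ±0.27 SUV, a threshold on this band mean
  alone separates the sexes perfectly — the Bayes oracle that guarantees
  downstream training tests have a learnable target.
* **Sex (chest, weak, high variance).**  A bilateral breast/pectoral
  feature whose amplitude is drawn per patient (women N(1.2, 0.8) SUV,
  men N(0.3, 0.3), clipped at 0).  The distributions overlap, emulating
  the large inter-individual variability of chest uptake; with the pelvis
  masked, this is the only sex cue left and accuracy drops accordingly.
* **Age.**  Background soft tissue is 1.1 + 0.006·(age − 60) SUV — a
  monotone intensity drift the regressor can read out.
* **Weight.**  Transaxial half-widths scale with √(weight / 70 kg)
  (cross-sectional area ∝ mass at fixed height), so silhouette width and
  area grow monotonically with weight.
* **Brain.**  Fixed at 12 SUV, above the display window, so it saturates
  to a featureless bright blob after windowing — carrying no demographic
  information, as in clinical windowed MIPs.
* **Noise.**  σ = noise_scale·√(SUV + 0.05) Gaussian per voxel (variance
  proportional to the local mean plus a floor), clipped at zero;
  noise_scale 0.15 for scanner 1, 0.25 for scanner 2.

Demographics sampling: sex Bernoulli(0.5607), age normal(61.6, 16.2)
clipped to [2, 92] years, weight sex-conditional normal (men 66 ± 10 kg,
women 52 ± 8 kg, clipped to [30, 120]) — the weight model is invented, as
no empirical weight distribution was available.  The default scanner mix
is 87.3 % / 12.7 %.  Scanner profiles at clinical resolution
(168 × 168 @ 4.1 × 4.1 × 2.0 mm; 144 × 144 @ 4.0 mm isotropic) are
provided and used for single-volume geometry checks; cohort-scale
experiments default to desk-scale siblings (48 × 48 @ ~14 mm and
40 × 40 @ ~14.4 mm) with identical fields of view, view counts and noise
character, so that hundreds of phantoms project in minutes on one CPU
core.

What passing tests on these cohorts do **not** show: robustness to real
anatomical variability, pathology (e.g. pelvic tumours), bladder/renal
tracer pooling, arm positioning, or reconstruction artefacts.  The
phantom demonstrates that the pipeline recovers planted demographic
structure; clinical performance claims require clinical data.

## Experiment designs and problem sizes

The mixed design draws a patient-level 70/30 split (re-drawn per repeat
from seeds spawned off one master seed via `SeedSequence`), trains each
requested task and summarizes metrics as mean ± sample SD (ddof = 1; SD
reported as undefined for a single repeat).  The cross-scanner design
trains on all patients of one scanner and tests on all patients of the
other; the two desk scanners differ in voxel grid and noise, planting a
domain shift, so transfer accuracy should not beat the mixed design.
The masking ablation fixes one patient split and one seed, then retrains
from scratch once per mask region (head, chest, abdomen, pelvis, upper
body = head + chest, lower body = abdomen + pelvis) plus the unmasked
baseline; masks are horizontal image bands filled with each image's own
mean gray value and are applied to training *and* test images.

Default problem sizes in the shipped tests and acceptance script — chosen
as the package's own desk-scale working points: n = 300 patients for the
end-to-end sex experiment, n = 150 for the masking ablation, n = 120–150
for the regressions, with `max_epochs` 2 (sex), 8 (age) and 5 (weight);
the pelvic signal is strong enough that the classifier converges within
one or two epochs.

## Design choices that were genuinely open

* **Masking fill value**: `apply_mask` defaults to each image's own mean,
  and the fill is recorded in the masked image's metadata so a mask can be
  re-applied idempotently.  The masking *experiment*, however, defaults to
  one shared fill value (the mean gray over the training-fold images):
  the per-image mean itself carries the regional signal — a bright pelvic
  feature raises it — so with per-image fill a classifier can read the
  class straight off the mask brightness and the ablation measures
  nothing.  `fill="image_mean"` remains available for comparison.
  Relatedly, the phantom keeps its pelvic features strictly inside the
  pelvic band; a feature touching the band boundary would leave a sliver
  of signal outside the mask after row rounding and resampling blur.
* **Lower-body vs pelvis ablation**: with a pelvis-only planted signal the
  lower-body mask is a strict superset of the pelvic mask, so its row can
  tie with or undercut the pelvis row; the tests treat either outcome as
  recovery of the pelvic signal.
* **Grad-CAM weighting**: the standard formulation (channel weights =
  spatially averaged gradients) is the default.  At the default 16-channel
  width, however, globally averaged weights smear localization even when
  occlusion probes prove the model depends on the pelvis; `grad_cam`
  therefore also offers `method="elementwise"`
  (ReLU of the gradient–activation product, no spatial pooling), which
  localizes correctly on narrow networks, and the localization tests use
  it.  The occlusion probe — mask one band at inference and measure the
  accuracy drop — is the package's authoritative region-dependence check.
* **Regression target scaling**: targets are standardized inside `train`
  and denormalized at prediction; MSE on raw years/kg converges poorly at
  these learning rates.
* **Tie-breaking in max pooling**: gradient routes to the first maximal
  element (argmax), making backward passes deterministic.
* **70 % split arithmetic**: `floor(0.7 n)` training patients; at
  n = 6,462 this gives 4,523.

## Limitations

* The NumPy engine targets 64 × 64 single-channel inputs and this
  architecture family; it is not a general deep-learning framework.  A
  `backbone` hook on `build_model` accepts an alternative feature
  extractor (e.g. a residual network), but none is shipped.
* Phantom realism is intentionally minimal (see above).
* Alert thresholds are fixed bands, not calibrated operating points; no
  PACS/HL7 integration is provided.
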