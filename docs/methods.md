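# Methods

This note documents the models, rules, numerical choices and known
limitations of `ezar`, in the spirit of a methods appendix.

## Coordinate and data conventions

All grids are 0-based. Within a B-scan, row 0 is at the vitreous and rows
increase toward the choroid; surface positions are real-valued (sub-pixel)
row coordinates, and rasterisation rounds half-up. The en-face frame is
`(B-scan index, A-scan index)`; every en-face product — thickness maps,
flag maps, ground-truth labels — shares it. Intervals are half-open.
Absence of the EZ or RPE surface at a column is encoded as NaN; ONL and BM
are never absent. The default axial sampling is 3.87 µm/px (typical
Spectralis optics); no claim of device fidelity is made and every scale is
configurable per volume through `ScanGeometry`.

## Thickness and the attenuation rules

Per column, `t = (row(lower) − row(upper)) · axial_scale` in µm. A column
where the upper surface of a pair is absent (EZ for EZ–RPE, RPE for
RPE–BM) — or where both are absent — has thickness 0: absence of a band is
read as total attenuation of that band. Real-valued surfaces make exact
zeros fragile, so "0 µm" is implemented as `t ≤ 1e-6 µm`.

Rule thresholds (defaults, configurable via `RuleThresholds`):

- **EZ At-Risk**: `t_EZ-RPE ≤ 10 µm`, *inclusive*, excluding GA columns.
- **Partial EZ attenuation**: `t_EZ-RPE < 20 µm`, *strict*. Zero-thickness
  columns are included, so partial is a superset of total and the
  invariant `%total ≤ %partial` is testable. Whether GA columns should be
  excluded from the partial numerator is a judgment call; they are
  included here, and the GA map is available to callers who want the
  complement.
- **GA**: both pair thicknesses 0. No minimum lateral extent by default;
  consensus-style definitions often require ~250 µm of contiguous width,
  so a `ga_min_extent` parameter exists (runs shorter than
  `extent/lateral_scale` columns within a B-scan are cleared) but defaults
  to 0 rather than silently imposing a convention.

Training masks place, for every flagged column, a `band_px = 10` pixel
vertical band centered on the half-up-rounded EZ row — 5 rows above, 5
below, clipped at image borders. Where a flagged column has no EZ (total
attenuation outside detected GA) the band centers on the RPE row. There is
no lateral dilation: the band's lateral extent is exactly the flagged
columns.

## Biomarkers

Percentage areas divide by **all** A-scan columns of the volume's en-face
field; a whole-field denominator is the only choice that makes values
comparable across eyes (per-B-scan variants, used in B-scan-level
evaluation, divide by that B-scan's columns). The central subfield is the
fovea-centered disc of radius 0.5 mm (inclusive boundary); central
subfield means are unweighted arithmetic means over its columns. sfGA (GA
on the foveal B-scan) and fovea-threatening GA (GA inside the central
subfield) are computed independently — neither implies the other, since a
lesion can cross the foveal B-scan far from the fovea, or approach the
fovea between B-scans. GA area is `(flagged columns) · lateral_scale ·
bscan_spacing`, i.e. each column counts as one en-face grid cell.

## Synthetic eyes

The generator emulates a 6 × 6 mm macular cube (presets for 49-, 97- and
128-B-scan rasters; tests use a reduced 32 × 128 × 128 custom grid).
Components, each drawn from an independent seeded stream so that raising
one lesion count leaves the others bit-identical (and earlier lesions of
the same type unchanged — the superset policy behind the monotonicity
test):

- **BM**: a base depth at 65 % of the B-scan plus ≤ 5 low-frequency cosine
  terms of bounded amplitude (≤ 2 % of depth) — smooth, seedable, no
  spline dependency.
- **RPE**: BM minus the baseline RPE–BM thickness (25 µm), elevated by
  Gaussian drusen (height 20–60 µm, radius 100–300 µm, σ = radius/2).
- **EZ**: RPE minus a thickness field that starts at the 35 µm baseline
  and is reduced inside attenuation patches by Gaussian radial factors
  (depth 0.8–1.0 of baseline at center, radius 400–900 µm). Six patches
  per eye by default, which yields baseline EZ At-Risk areas of roughly
  3–5 % of the field — the single-digit percentage range reported for
  eyes with nonexudative AMD.
- **GA**: elliptical en-face regions (radius 300–700 µm) where EZ and RPE
  are marked absent; GA overrides attenuation (absence wins).
- **ONL**: a fixed 80 µm above the EZ. An optional foveal pit (60 µm
  Gaussian depression of all four surfaces, σ = 400 µm, on by default)
  keeps sfGA geometry visually sensible without affecting any thickness.

Rendering draws each present surface as a bright Gaussian band
(σ ≈ 1.3 px) over a dim background with a brighter choroid below BM;
sub-BM intensity in GA columns is multiplied by the hypertransmission
gain (default 2). Speckle is multiplicative: `I · max(0, 1 + σ·g)` with
standard-normal `g` and σ = 0.25, then clipped to [0, 1] — qualitatively
OCT-like, deliberately not a physical speckle model.

Ground truth is produced *only* by running the rule module on the
generated surfaces; the generator never labels pathology itself, so the
labels cannot drift from the rules.

What the generator does **not** emulate: real layer-segmentation errors,
vascular shadowing, motion artifacts, reticular pseudodrusen, realistic
speckle statistics, or inter-device contrast differences. Passing tests
therefore demonstrate the internal consistency and learnability of the
pipeline, not clinical-grade performance.

## Segmentation harness

The network is a U-shaped encoder–decoder: double 5 × 5 convolution
blocks with leaky-ReLU activations (negative slope 0.1), 2 × 2 max
pooling, nearest-neighbour upsampling with skip concatenation, a 1 × 1
sigmoid head. The leaky slope is not cosmetic: with hard ReLU the
adaptive optimizer's large first steps can silence every unit at once,
collapsing the network to a constant output from which zero gradients
offer no escape — a failure mode observed at some seeds. It is implemented directly in
numpy (im2col convolutions, analytic backpropagation, single-threaded,
float32) so training is exactly reproducible from the seed. The optimizer
is RMSprop (ρ = 0.9, ε = 1e-8); the loss is mean pixel-wise binary
cross-entropy. Max-pooling routes gradients to exactly one element per
window even under ties — ties are common after ReLU, and double-counting
them measurably biases the bias-gradients of layers above all-zero
regions.

Two presets share this architecture:

- **full-scale**: 256 × 256 inputs, 32 base filters, depth 4 —
  ≈ 2.2 × 10⁷ parameters. Constructed and parameter-counted in tests, not
  trained in CI.
- **desk**: 64 × 64 inputs, 8 base filters, depth 3 — ≈ 3.4 × 10⁵
  parameters, learning rate 1e-3, batch size 4, 200 samples per epoch,
  up to 8 epochs. Small batches buy more adaptive-gradient steps per
  epoch, which the sparse-positive objective needs to become confident
  in few epochs. This is the configuration the end-to-end study trains
  on a single CPU in a few minutes.

Each epoch draws `samples_per_epoch` examples with replacement; early
stopping triggers after `patience` consecutive epochs without a strictly
lower validation loss, and the best epoch's weights are restored. Before
the first step the sigmoid head's bias is set to the training masks'
base-rate logit (`log(p/(1-p))`, p clipped to [1e-4, 1-1e-4]): positive
pixels are sparse (a few percent), and a zero-initialised head otherwise
spends its early epochs pushing probabilities down and can stall with
every pixel below the 0.5 decision threshold despite good ranking.

Splitting is at the patient level: patients are shuffled by seed and cut
into 80/10/10 train/validation/test sets with largest-remainder rounding,
so all visits of a patient land in one set by construction.

Area measurement binarises the probability map, maps it back to the
original resolution through the stored scale record (nearest neighbour),
and keeps the full floating-point percentage; rounding happens only at
presentation (the CLI writes four decimals).

**Automatic retraining**: after the first round, 100 training examples
are sampled without replacement and profiled for Dice/F-scores
(two empty masks score 1.0 — perfect agreement on absence; empty vs
non-empty scores 0). The cut is the linear-interpolation 30th percentile;
examples *strictly below* the cut are appended once more to the training
set ("duplicated" read literally), and training reruns with the identical
configuration, continuing from the current weights
(`retrain_from_current=False` restarts from a fresh initialisation).
With 100 distinct scores exactly 30 fall strictly below the cut; with all
scores equal, none do.

## Evaluation

Three levels: volume (any B-scan with predicted area above `min_area`,
default 0 — any positive area counts), B-scan (same rule per B-scan
against "any ground-truth column"), and pixel (pooled confusion counts
plus an ROC over the pixel probabilities; AUC equals the Mann–Whitney
statistic with ties at ½). Agreement between predicted and ground-truth
per-B-scan area percentages uses ICC(2,1) — two-way random effects,
absolute agreement, single measures — computed from the two-rater ANOVA
mean squares, with the F test MSR/MSE on (n−1, n−1) degrees of freedom.
Absolute agreement is the right form for method-versus-truth comparisons
because it penalises constant offsets that Pearson correlation ignores;
the chosen form is recorded in the result object.

## Progression analytics

The synthetic cohort draws the six baseline biomarkers from a truncated
multivariate normal (attenuation percentages co-vary positively,
central-subfield thicknesses negatively with them; rejection sampling
with failure above 90 % rejection). Conversion to sfGA or
fovea-threatening GA is Bernoulli on a logistic link over standardised
features; the default coefficients make EZ At-Risk and total EZ–RPE
attenuation the dominant drivers, consistent with the biology the
biomarker targets. Five-year GA growth is `γ · pct_ez_at_risk + noise`
(γ = 0.15 mm²/%, σ = 0.5 mm²) floored at 0, and "showed growth" is
operationalised as growth > 0 mm² exactly.

Analysis uses Pearson correlation (two-sided), a Welch unequal-variance
t-test (the safer default when group variances are unknown), and a
random forest (500 trees by default; the multi-seed sweeps use 150 for
runtime) under stratified 10-fold cross-validation. Two CV-AUC summaries
are reported: the mean of per-fold AUCs, and the pooled AUC over each
sample's single out-of-fold score (the form used in the calibration
checks). Under the null the sampling sd of either summary is ≈ 0.056 at
n = 300 and ≈ 0.035 at n = 800 — cross-validated AUC is noticeably
noisier than a naive independent-sample calculation suggests, which is
why the calibration sweep uses the larger cohort. The mean ROC averages
fold-wise true/false positive rates over a fixed 101-point
probability-threshold grid, and the reported operating point maximises
sensitivity + specificity (Youden). Feature importance is *permutation* importance evaluated on the
held-out fold (AUC scoring, 10 repeats), averaged over folds and floored
at zero — permutation importance is preferred over impurity importance
because it is unbiased under feature-scale differences.

## Problem sizes and numerical choices

The acceptance study simulates 11 eyes of 32 B-scans (128 × 128 px each),
trains on 200 B-scans, validates on 32 and holds out 64; rule fuzzing
uses 100 random 6 × 20 thickness maps; the split-hygiene sweep uses 1,000
seeds over 57 patients; the progression sweeps use 20 seeds at n = 500
(driver recovery) and n = 800 (null calibration — sized so the ± 0.1
acceptance band on the null CV AUC probes calibration rather than the
estimator's sampling noise). Degenerate inputs are
handled explicitly: empty flag maps raise in `percentage_area`, an empty
central subfield raises, zero-variance inputs raise in the correlation
and are flagged in the ICC, and a training divergence (non-finite loss)
raises with epoch context rather than silently continuing.

## Known limitations

- The numpy network trains at desk scale only; no GPU path exists, and
  the full-scale preset, while constructible, is impractical to train
  here.
- Synthetic realism is limited as listed above; reported Dice/AUC/ICC
  values characterise the pipeline on its own generator, not on clinical
  images.
- GA detection is purely segmentation-based; intensity-based
  hypertransmission detection is out of scope (hypertransmission exists
  in the renderer but is not used by the rules).
- The exact layer schedule of the original 41-layer clinical network is
  not public; the harness keeps depth/filters/kernel configurable rather
  than guessing a specific schedule.
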