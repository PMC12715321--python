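# Methods

## The measurement model

A handwriting sheet is one A4 page (210 × 297 mm) carrying ten consecutive
repetitions of the same short written text, one per row.  All quantities are
computed on a calibrated raster: the calibration `c = 25.4 / dpi` mm per
pixel is carried as metadata from generation (or would come from the scan
resolution for real pages) and is never inferred from image content.

Two static measures summarize micrographia per subject and task:

* **Consistent micrographia** = ink area of row 1 (mm²).  Ink area is the
  count of ink pixels times `c²` — true inked area, not bounding-box or
  convex-hull area.  A mean-over-rows alternative is available but is not the
  default.
* **Sequence effect** = mean ink area of rows 6–10 divided by mean ink area
  of rows 1–5, dimensionless; < 1 indicates progressive shrinkage.  The
  orientation (last over first) is fixed so that shrinkage maps to values
  below 1.  It is invariant to calibration and to any common rescaling of
  row areas; areas scale as `c²` and lengths as `c` (scale equivariance,
  property-tested).

## Synthetic sheet generator

The generator exists so every downstream stage can be verified against exact
ground truth, with cohort-level parameter distributions chosen to emulate
clinical HS and PD handwriting statistics.

**Cohort sampling.**  Each subject draws a base area `A` (target mean ink
area of rows 1–5, mm²) and a sequence effect `s` from per-group normal
distributions, truncated below at 10% of the group mean (the configured SDs
are large relative to the means, and areas must stay positive).  Defaults:
HS area 126.72 ± 44.85 mm², PD-OFF 89.78 ± 26.37 (with ON-state and
early/mid-advanced-stage variants configured analogously); sequence effect
HS 1.05 ± 0.16, PD-OFF 0.92 ± 0.23.  Stage-specific and ON-state sequence
distributions are not separately known, so all PD variants reuse the PD-OFF
values.  The OFF/ON contrast is a configurable mean shift, 0 by default, and
OFF and ON cohorts are generated as distinct subjects: class labels live at
the subject level throughout the pipeline, which rules out one subject
carrying two classes.

**Row targets.**  Row `r` (1-based) gets target area `A · g(r)` with
`g(r) = a·ρ^(r−1)` geometric, normalized so that the mean of `g` over rows
1–5 is 1 and the ratio of means (rows 6–10 over rows 1–5) equals `s`; hence
`ρ = s^(1/5)` for ten rows.

**Rendering.**  A row is a parametric cursive-like curve (two superimposed
sinusoidal harmonics with seeded phases) rasterized as a one-pixel skeleton
inside the row's band, then thickened: the ink mask is exactly the `n`
pixels closest to the skeleton (Euclidean distance transform), with
`n = round(target area / c²)`.  This makes the realized binarized area match
the target to sub-pixel rounding (the ≤ 2% contract holds trivially), is
strictly monotone in the target, and needs no font assets.  Boundary ties at
equal distance are broken deterministically left-to-right so the stroke
stays compact.  Letter size, not pen width, carries the area signal: the
curve's extent, amplitude and wavelength all scale with
`sqrt(target / 110 mm²)`, so small rows are written small at a roughly
constant ballpoint-like stroke width (~0.5 mm), which is how micrographia
presents physically.  Writing starts at the left margin of each band.  A row
whose target exceeds the band capacity, or falls below the area of the
one-pixel skeleton (possible only at coarse resolutions), raises a
generation error naming the row.  Default resolution is 300 dpi
(A4 → 2480 × 3508 px); 150 dpi is a practical lower bound before the
minimal-stroke constraint bites for the smallest PD rows.

**Scan artifacts** are applied in fixed order — rotation (uniform in
±`rotation_deg`, ≤ 3°), multiplicative illumination gradient (≤ 20% of the
dynamic range, random direction), additive Gaussian noise (≤ 5% of range) —
all deterministic under a seed.  Defaults: 1.5°, 10%, 2%.

## Preprocessing

**Illumination flattening** estimates the paper background by max-pooling
plus grayscale closing at reduced resolution (window 3 mm, wider than any
stroke) and rescales the page so the background is uniform white; a clean
page passes through unchanged up to rounding.

**Deskew** finds the rotation (±3°, coarse 0.5° grid then 0.1° refinement)
that maximizes the variance of the horizontal ink-projection profile on a
downsampled binary mask, and rotates the flattened page by that angle.

**Row segmentation** binarizes the page, smooths the per-scanline ink counts
(Gaussian, 0.5 mm), takes maximal runs of inked scanlines, merges runs
separated by gaps under 2 mm, and drops bands under 2 mm high.  Exactly the
expected number of bands must remain, else a segmentation error reports the
count found (pages failing segmentation are skipped and counted, never
imputed).  Boxes share one horizontal frame — the full ink column range of
the page — so the ten crops of a page remain mutually to scale; row length
and letter size are signal and must not be normalized away per row.

**Instance crops** for classification are padded with background to the
target aspect ratio (split equally), resized, and min-max normalized to
[0, 1] with ink dark; a constant crop maps to zeros.

**Area measurement under artifacts.**  Ink areas are counted on a page that
has been resampled only once: rows are located on the deskewed copy, the
band regions are mapped back to the flattened original by nearest-neighbor
rotation of a label image, and ink is counted inside each band there.
Rotating the intensities a second time would soften thin strokes enough to
bias the counted area by tens of percent.  With this scheme the full
pipeline recovers per-row areas within 2% on clean renders and within 5%
under default scan artifacts (tested).

## Binarization

The global ink threshold is the midpoint between the robust ink and paper
levels (0.1 and 99.9 intensity percentiles).  Thresholding at the 50% edge
level keeps the counted area unbiased to first order when stroke edges are
softened by resampling; a between-class-variance (Otsu) split — available as
`method="otsu"` — drifts into the blur halo of thin strokes under such
conditions and inflates areas, because the ink class is a small fraction of
the crop.  On clean bilevel pages the two rules coincide.  Connected
components smaller than 0.05 mm² are removed as scan noise (a configurable
default, not a measured fact about any scanner).

## Classifier

The default scorer is a small convolutional network trained from scratch in
pure numpy: one 5×5 convolution (8 filters) → ReLU → 4×4 average pooling →
dense layer (width 16) → ReLU → 2-way softmax, minibatch SGD (learning rate
0.1, batch 32, 8 epochs by default) on 32×96 instances with inverse-
frequency class weighting (cohorts are imbalanced, e.g. 57 vs 25).  Weight
initialization, batch order, and therefore predictions are fully determined
by the seed.  An alternative `pretrained_plugin` backbone accepts any frozen
feature-extraction callable and trains only a logistic head on standardized
features — the frozen-backbone + linear-head transfer scheme — so a large
pretrained network can be plugged in without being a dependency.

**Cross-validation** is patient-disjoint and stratified: subjects of each
class are shuffled (seeded) and dealt round-robin to folds, so per class the
fold sizes differ by at most one subject, and all instances of a subject
share its fold.  Each instance is scored exactly once, by the model whose
validation fold holds its subject.  The per-patient **LR score** is the mean
of the subject's out-of-fold instance probabilities.  Averaging predictions
from models trained on a patient's own rows would leak identity and is
rejected by construction.  With folds equal to the number of subjects the
scheme degenerates to leave-one-subject-out and all contracts still hold.

## Diagnostics

ROC thresholds are the midpoints between adjacent distinct scores plus one
sentinel below and one above; a case is called positive when its score
exceeds the threshold.  AUC is the trapezoidal integral over (FPR, TPR)
sorted lexicographically, which equals the Mann-Whitney rank statistic
`P(s⁺ > s⁻) + ½·P(s⁺ = s⁻)` exactly (property-tested against the exhaustive
pairwise count).  The Youden index is `max(sens + spec − 1)` with ties
broken toward the lower threshold (higher sensitivity); its maximizer is the
associated criterion.  PPV, NPV and accuracy at an operating point use the
subject counts of the comparison as prevalence:

```
accuracy = (sens·n⁺ + spec·n⁻) / (n⁺ + n⁻)
PPV = sens·n⁺ / (sens·n⁺ + (1−spec)·n⁻)      (NaN when the denominator is 0)
NPV = spec·n⁻ / (spec·n⁻ + (1−sens)·n⁺)
```

Patient-level ROC is primary (the LR is patient-specific); no confidence
intervals are computed by default.

## Reporting layer

Group comparisons dispatch on design × family: unpaired/paired Student t
(classic equal-variance form for unpaired), Mann-Whitney U, Wilcoxon
signed-rank, and chi-square on contingency counts — all two-sided, α = 0.05,
no multiple-testing correction by default (a Benjamini-Hochberg helper
exists).  Correlations are Spearman's rank with average ranks for ties.
Statistics are verified in tests against their textbook formulas on fixed
vectors, and the type-I error of the unpaired t is checked to sit near α
over 1000 null replicates.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: parameter
recovery uses 19 HS and 15 PD subjects (the subset size of the motivating
cohort design) rendered cleanly at 300 dpi; the end-to-end classification
check uses 10 + 10 well-separated subjects at 200 dpi with 5 folds and 4
epochs; the full simulated study in `analysis/` defaults to 25 HS + 57 PD.
All randomness flows from named seeds (generation, folds, training), and
every run directory carries its serialized configuration.

## What the generator does and does not emulate

It emulates page geometry, row layout, calibrated ink-area distributions and
their group differences, within-sheet size decay, and smartphone-scan
degradation.  It does not emulate letterforms, language content, tremor,
stroke-level kinematics (velocity, pressure, fluency), retouching, paper
texture, or perspective distortion from handheld capture.  Passing tests
therefore demonstrate that the measurement and classification pipeline is
correct and unbiased on controlled inputs with known truth — not that the
classifier's synthetic-cohort performance transfers to real patient
handwriting, where the class signal is richer but subtler.  The perceptual
(human-rated) scale of the original design is out of scope; automated row
geometry (height/length of the ink bounding box) stands in as the objective
proxy and is labelled as such in reports.

## Known limitations

* Binary-count areas remain slightly positively biased (≲ 5%) under combined
  rotation + interpolation artifacts; the bias grows for strokes much
  thinner than ~3 px, so very low dpi with small writing is discouraged.
* Skew estimation is accurate to ~0.1–0.3°; residual tilt is handled by the
  single-resampling measurement scheme rather than by a tighter estimator.
* The numpy CNN is deliberately small; it is a correctness- and
  protocol-testing scorer, not a competitive image model.
* OFF/ON cohorts are independent subjects, so within-subject treatment
  effects (paired designs) are only approximated at the group level.
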