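# Methods

This note records the modeling choices behind `pupilforest`, the parameters
that matter, and what the synthetic experiments do and do not establish.

## Displacement regression

Each regression tree maps a flattened gray-scale patch (intensities in
[0, 1]) to a 2-D displacement toward the pupil center, expressed in
eye-corner-distance units so the model is scale-free. The two displacement
components are regressed jointly: a node's split score is the
variance-reduction gain with child sums of squared errors weighted by
`|S_child| / |S_parent|`, pooling squared deviations of dx and dy. Candidate
thresholds are nearest-rank empirical quantiles of the feature among the
node's samples (16 by default), and each node draws `ceil(sqrt(D))` candidate
features without replacement. Ties in gain resolve to the lowest feature
index, then the lowest threshold; the vectorized search re-scores near-ties
with the canonical scalar arithmetic so the outcome is identical to an
exhaustive enumeration (mirrored partitions reached from different features
would otherwise flip on 1-ulp differences).

Defaults: `max_depth = 6`, `min_samples_leaf = 5` (a node splits only when it
holds at least twice that), bootstrap bagging at fraction 1.0. Shallow trees
keep the induced rules at four to six conditions, which is what makes the
rule listing legible.

**Leaf model.** Leaves store their mean displacement. The default predictor is
that constant; an affine leaf (ordinary least squares on a leaf-local PCA
basis of at most 8 directions, ridge-damped at 1e-6, with a constant fallback
whenever the leaf holds no more than twice the reduced dimensionality or the
features are rank-deficient) is available via `TreeConfig(leaf_model="linear")`.
The constant default was chosen deliberately: distilled rules must freeze each
leaf to a single THEN value to remain pure IF-THEN records, and keeping the
cascade's leaves constant too makes rule-set inference *exactly* (bit-level)
equal to cascade inference rather than approximately so. On raw intensity
patches the affine term buys little at these leaf sizes.

## Cascade

Default schedule (configurable): 5 forests × 10 trees, then 10 × 20, then
15 × 30, with crop windows of 1.0, 0.6, and 0.35 eye-corner distances and a
24 × 24 resampled patch at every layer. The ensemble grows and the window
shrinks with depth because early layers solve a coarse, high-variance problem
and late layers a fine, low-variance one. Layer averaging is the mean of
forest means; with equal tree counts per forest this equals the pooled tree
mean. Patches are re-extracted at the updated positions between layers, and
per-layer targets are the remaining normalized residuals.

Left and right eyes are pooled into one model by mirroring right-eye patches
horizontally and negating dx (equivalent to reflecting the image about the
patch center), which doubles the effective training set; the mirror is undone
at prediction time. Out-of-bounds pixels are mirrored at the image border;
bilinear interpolation resamples the crop; coordinates are 0-based pixels,
x rightward, y downward, patches row-major.

Training residuals (mean Euclidean distance to ground truth, in pixels) are
recorded after initialization and after each layer; they are non-increasing
on the training set, which the tests assert non-strictly.

## Rules and distillation

One rule per leaf, conditions accumulated root-to-leaf ("<=" left, ">"
right). Importance is assigned per path *edge*: the Euclidean magnitude of
the change in mean displacement from parent to child, with the edge into the
leaf included. A rule with c conditions therefore carries c importances and
its contribution is their mean. Scoring edges rather than internal nodes
only is a deliberate resolution of an ambiguity: a depth-1 tree would
otherwise have no importances at all and every shallow rule would score 0,
making contribution ranking vacuous exactly where rules are most readable.
The magnitude-then-average order makes the score independent of rule order
and of other trees' contents.

Distillation keeps the top `round(keep_ratio · n)` rules per tree
(half-up rounding, floor of one rule per tree), ties broken by original leaf
order. `keep_ratio` is the retained fraction; the CLI also accepts
`--remove-percent`. A uniform ratio is the default; per-tree ratios can be
had by distilling layers separately.

**Inference after pruning.** The original trees partition feature space, so
before distillation exactly one rule per tree fires. A sample routed to a
deleted rule makes that tree *abstain*; forests average non-abstaining trees,
layers average non-abstaining forests, and a fully abstaining layer
contributes zero displacement. Abstention avoids inventing surrogate outputs
for deleted regions and degrades smoothly as the keep ratio drops.

**Size accounting** (convention stated in the serialized header): parameters
count 2 per condition plus 2 per rule output; operations per inference count
the longest retained rule per tree (worst-case comparisons) plus one
accumulate per tree and per forest.

## Tracking

Three particles by default, interpolation weights evenly spaced in
[0.5, 1] — biased toward the new prediction but anchored to history — with
isotropic Gaussian noise of 2 px. Selection is the plain L2 nearest particle
to the previous position (ties to the lowest index); there are no particle
weights or resampling. Eye closure is decided by the eye-aspect ratio of the
six landmarks, threshold 0.12 (open at the boundary); closed frames carry the
previous position forward, and the first frame bootstraps from the raw
prediction without a check. All of the interpolation weights, the noise
scale, and the closure threshold are configurable; the defaults are the
values used throughout the tests.

## Synthetic data

The renderer draws, per frame, two almond-shaped eyes (parabolic lid arcs,
open half-height 0.25 × eye width) on a skin-tone background, an iris disk at
2.2 × the pupil radius, a darker concentric pupil, an upper lid descending
with `lid_closure`, a linear horizontal illumination gradient, slight
Gaussian blur, and additive pixel noise. Both eyes share the gaze offset
(conjugate gaze), and the inter-pupil distance is ≈ 2.3 × the eye-corner
distance, matching adult facial proportions (~63 mm vs ~28 mm); this ratio
matters because the evaluation metric normalizes by the inter-pupil
distance. Dataset sampling defaults: pupil offset uniform in [−0.3, 0.3]²
of the eye half-box, pupil radius fraction in [0.08, 0.15], noise standard
deviation in [0, 0.05], illumination gradient in [−0.2, 0.2], and full lid
closure with probability 0.1. Sequences move the offset by a reflective
Gaussian random walk (σ = 0.03 per frame by default) with optional blink
frames.

What the renderer does *not* emulate: glasses and specular reflections,
eyebrow/hair occlusion, head pose, camera blur and compression, and
person-specific appearance. Passing the recovery experiments therefore shows
that the pipeline implements its contracts and can recover known geometry
from images with the assumed intensity ordering (pupil < iris < sclera); it
does not certify accuracy on photographic benchmarks.

Closed-eye frames are kept in both training and test sets. With the lid
down, the patch carries no pupil information, so the model regresses toward
the mean offset; under the anthropometric inter-pupil normalization most
such frames still land within e_d ≤ 0.1 and a majority within 0.05, which is
visible as the gap between the 0.025 and 0.05 accuracy columns.

## Problem sizes and numerics

The recovery experiment trains the default cascade on 400 rendered frames
(800 eyes after left/right pooling) and tests on 100 held-out frames — large
enough for stable accuracy estimates at the 1% granularity reported, small
enough that the full pipeline (train, distill at three ratios, evaluate,
track 50 frames) completes in a few minutes on one CPU. All randomness flows
through `numpy.random.SeedSequence` spawning, so identical seeds give
byte-identical serialized models, reports, and track CSVs; model JSON uses
shortest round-trip float formatting and re-serializes bit-exactly.
Degenerate inputs are defined rather than exceptional: empty split children
score 0 gain, constant targets make leaves, coincident eye corners and
coincident ground-truth pupils raise errors, and a keep ratio outside (0, 1]
is rejected.

## Known limitations

- Rules are pruned independently per tree; redundancy *across* trees is not
  detected or shared.
- Abstention after heavy pruning biases layer averages toward the surviving
  rules; there is no surrogate output for deleted regions.
- The closed-eye detector assumes the six-landmark layout; real landmark
  noise is not modeled.
- Classification trees, gradient boosting, face/landmark detection, 3-D gaze,
  and energy measurement are out of scope.
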