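# Methods

This note documents the models, parameters and design choices behind
`mammodelta`, and what its synthetic-cohort tests do and do not establish.

## Problem setting

Input is a per-patient triplet of screening rounds (prior, current, future),
each with two views (CC, MLO). The future round exists only at training
time: for malignant cases it carries the biopsy-confirmed mass outline. The
task is to decide, per candidate region of the current/prior subtraction
image, whether that region will develop into a mass by the next round.

## Preprocessing

All rounds pass through the same chain: min–max normalization to [0, 1]
(a constant image maps to zeros), CLAHE (clip limit 0.01, 8×8 tiles),
gamma correction (γ = 0.8, mild brightening), and border removal (5-px
frame zeroed). The first two parameters follow common mammography practice
and are config-exposed; none of them is critical to the downstream logic,
which only assumes monotone intensity maps. Border removal runs *before*
breast segmentation so scanner-edge artifacts cannot win the
largest-component rule. The breast mask is the largest 8-connected
component above a small adaptive threshold (5% of the intensity range above
the minimum), hole-filled.

## Registration

Classic (Thirion) demons with Gaussian regularization of the displacement
field, run coarse-to-fine over a 3-level pyramid with 50/30/10 iterations
and smoothing σ = 2 px. The numerical core is SimpleITK's demons filter;
the pyramid, the displacement-field convention (per-pixel (row, col)
offsets on the fixed grid, backward warping, out-of-bounds → 0) and the
mask-propagation rule (warp the binary mask as a float image, re-threshold
at 0.5) are defined here. The current round is always the fixed image;
future and prior are moving. Images of unequal size are zero-padded
bottom/right to a common shape first.

Measured on fields of the same family the synthetic cohort uses
(Gaussian-smoothed random fields, amplitude ≤ 8 px, smoothness 20–40 px),
the mean endpoint error is ≈ 0.03–0.04 px and registration is exactly
deterministic. Registration of an image to itself yields mean displacement
< 0.1 px.

## Subtraction and enhancement

The registered prior is subtracted from the current image; negative values
are clipped by default because a new mass is a new *bright* structure
(a signed mode is available for research use). Unsharp masking
(`out = img + amount·(img − blur(img, σ=radius))`, radius 5 px, amount 1.0)
boosts the high frequencies that carry mass edges; output is clipped to
[0, 1]. The contrast ratio used for reporting is mean intensity inside a
mass annotation over mean intensity in the surrounding 10-px annulus, with
the background mean floored at 10⁻⁶.

## Segmentation

Three steps on the enhanced subtraction image:

1. **Thresholding.** Binary at a global threshold. When set to `auto`, the
   threshold is chosen from candidate percentiles
   {80, 85, 90, 92.5, 95, 97.5, 99} of the pooled nonzero intensities by
   maximizing ground-truth recovery (fraction of annotated mass components
   hit by at least one ROI); ties resolve to the lower threshold. The two
   sub-90 candidates matter at desk scale: unsharp masking amplifies only
   the *edges* of broad precursor blobs, so their interiors sit below the
   90th percentile.
2. **Morphology.** Erosion with a 2-px disk (drops isolated
   registration/threshold debris) then closing with a 10-px disk (merges
   the constituents of one mass). Semantics are set morphology on the
   infinite plane with background outside the frame; the closing is
   computed on a frame padded by its radius. Both radii are the printed
   values of the workflow being implemented and are assumed to be native
   pixels.
3. **Periphery removal.** Any component outside the breast mask or
   intersecting the 15-px band inside the breast border is deleted whole —
   masses cannot form in the skin line, and subtraction is brightest there
   because breast-outline mismatch between rounds is irreducible.

Surviving 8-connected components with area ≥ 9 px² are the ROIs, ordered by
raster position of their bounding boxes. An ROI is labeled *future
malignant* when ≥ 25% of its support overlaps the propagated ground-truth
mask (the workflow does not define this overlap rule; 25% is a deliberate,
config-exposed choice — by construction the precursor ROI either hits the
propagated disk squarely or misses it, so the label is insensitive to the
exact fraction).

## Features (98)

The registry is fixed and ordered: 15 shape + 9 intensity/first-order +
72 GLCM + 2 epidemiological = 98. The shape set is standard region
properties plus Circularity = 4πA/P², Compactness = P²/(4πA) and Shape
Ratio = major/minor axis. First-order statistics are computed over the ROI
pixels of the enhanced subtraction image; Smoothness = 1 − 1/(1 + Var),
Entropy is Shannon entropy (bits) over a 32-bin histogram. GLCM features
use symmetric, normalized co-occurrence matrices on the ROI's bounding-box
patch quantized to 32 gray levels over the patch's own range — this makes
texture invariant to additive intensity shifts, which is the property the
tests assert. For each offset D ∈ {5, 15, 25} px and base statistic
∈ {Contrast, Correlation, Energy, Homogeneity}: four directional values
(0°, 45°, 90°, 135°) plus their mean and STD, i.e. 24 values per offset. A
constant patch is degenerate: Contrast 0, Energy 1, Homogeneity 1, and
Correlation *defined* as 0. Patches smaller than an offset are zero-padded
and flagged. The total of 98 reproduces the published count and contains
every published feature name; the exact complement beyond the named ones is
a reconstruction, not a claim about the original list.

## Feature selection

Eight rankers produce ordered top-k lists (k = 25 by default): Welch
t-statistic magnitude; greedy mRMR (MID scheme — relevance by mutual
information with the label minus mean pairwise mutual information with the
already-selected set, estimated on 16-bin discretized features);
impurity importances from extra trees and random forests; gain importances
from gradient-boosted trees; univariate ANOVA-F ranking; and sequential
forward/backward wrapper selection around an LDA base learner with internal
5-fold CV. Zero-variance features are excluded up front. The majority rule
keeps features appearing in ≥ `min_votes` lists; the default of 4 of 8 is
the unique threshold at which merging the eight published ranked lists
(shipped as package data) returns exactly the published 14-feature
selection — a useful property: the vote count of each feature is
independent of how the published table's ragged columns are laid out, as
long as no list repeats a feature.

## Class balancing

ADASYN oversamples the minority (future-malignant) class inside each
training fold only: each minority point receives synthetic offspring in
proportion to the majority fraction among its 5 nearest neighbors, each
generated by uniform interpolation toward a random minority neighbor.
Originals are retained unchanged; the output ratio is within 10% of 1:1.
If the minority class is smaller than the neighborhood size the balancer
falls back to random duplication with a warning.

## Classifiers and evaluation

Twelve families are available (random forest, gradient boosting, MLP,
k-NN, AdaBoost, SVM, naive Bayes, a fixed small feed-forward network, LDA,
QDA, extra trees, and voting ensembles). The fixed network is one hidden
layer (64 ReLU units), softmax-style output, Adam, batch 128, learning
rate 10⁻⁴, 100 epochs. k-NN is restricted to k ∈ {1,3,5,7,9,11}; SVM
kernels to linear/polynomial/RBF. For soft voting, SVM probabilities come
from a single Platt scaling of the training margins (one SVC fit plus a
1-D logistic) rather than the 5-fold internal refit of
`probability=True` — numerically equivalent for ranking purposes and ~6×
cheaper, which is what makes 75-fold LOPO tractable at desk scale.

Cross-validation is always grouped by patient: LOPO (75 folds) or k-fold
(k = 5 or 15) with patients shuffled by the run seed and folds stratified
by the patient-level case label. Within each fold, the scaler, ADASYN and
(in per-fold selection mode) the feature ranking see training patients
only; this is enforced by an assertion in the loop and audited by a
corruption test (perturbing a held-out patient's rows leaves every
training-side artifact of that fold bit-identical). Out-of-fold
predictions are pooled; sensitivity/specificity/accuracy come from pooled
confusion counts, AUC from the rank statistic over pooled scores (pooled
rather than fold-averaged — a deliberate choice), false positives per
image divide FP by the number of subtraction images, and a malignant
patient counts as detected if any of their true ROIs in either view is
flagged. Soft votes threshold at 0.5 and hard-vote ties go to the positive
class: ranking is sensitivity-first. Classifier pairs are compared with
the continuity-corrected McNemar chi-square on the discordant
correct/incorrect pairs; the multi-classifier form applies it pairwise
against a reference with Bonferroni adjustment (the exact published
"extended" formulation is not specified; this is the documented
interpretation).

Feature selection is *global by default* (the fixed 14-feature reference
subset), reproducing a workflow in which one selection table is reported
for the whole study; a per-fold mode re-runs the six non-wrapper rankers
inside every training fold for fully nested selection.

## Synthetic cohort

The generator emulates the study population: 75 patients (34 malignant),
ages uniform on [46, 79], BI-RADS densities drawn with probabilities
13/29/29/4 (a/b/c/d) out of 75, two views, three rounds at 256×256. Each
view has a half-ellipse breast support (MLO adds a pectoral wedge),
multi-scale Gaussian background texture, and rounds related by
Gaussian-smoothed random deformation fields (amplitude 8 px, smoothness
40 px — plausible compression/positioning differences at this scale).
Benign interval change is modeled as Poisson-count clutter blobs
(rate 90/round, radius 4–6.5 px, contrast 0.15–0.28, smooth profile)
placed by dart-throwing with 24-px minimum separation; placement differs
between rounds, so subtraction sees them. Malignant cases get a bright
mass (radius 9–15 px, contrast 0.4, plateau profile — a dense lump with a
defined border) in the future round and a faint precursor (contrast 0.15,
same plateau profile, same deformation-consistent location) in the current
round; the injected future-mass support is the expert-style annotation and
the precursor disk is retained as generator truth. Per-round white noise
(σ = 0.01) tops it off. All randomness flows from one seed;
`(seed, patient_index)` reproduces a case bitwise.

**Scale calibration.** At 256×256 the 10-px closing merges any two blobs
whose centers are closer than ≈ 28 px, which geometrically caps candidate
density near ~25 ROIs/image; the ~49 ROIs/image of a full-resolution
clinical workflow arises on images roughly 10× larger. The defaults above
were calibrated once so that (i) mean ROI density lands in the 20–80 band,
(ii) every malignant case's precursor survives default segmentation in at
least one view, and (iii) the end-to-end benchmark is achievable; they are
study conditions, not tuning knobs, and the tests run against them
unchanged. On the default cohort (seed 0) the full pipeline yields ≈ 23
ROIs/image (≈ 3 500 ROIs total), per-ROI sensitivity 93.7% at 0.21 false
positives per image, AUC 0.98, and ground-truth propagation lands within
the mass radius for 68/68 malignant views.

**What the generator does not model** — and hence what passing tests do
not show about clinical data: X-ray physics (scatter, dose, detector
response), vendor post-processing, pectoral-muscle and nipple anatomy,
dense-tissue camouflage, spiculated or non-focal masses, benign masses
that persist across rounds, and annotation disagreement between readers.
Synthetic precursors are focal, round and geometrically distinct from
clutter; real precursor separability is far harder. The benchmark
therefore validates pipeline correctness and leakage-free evaluation, not
clinical accuracy.

## Numerical and degenerate-input rules

- Constant images: normalization → zeros; CLAHE → unchanged; GLCM →
  degenerate rule above.
- Empty propagated masks (mass warped out of frame) raise and are logged
  per case; pipeline runs skip-and-log rather than abort.
- Thresholds are clamped to (10⁻⁶, 1 − 10⁻⁶); background means in the
  contrast ratio are floored at 10⁻⁶; Shape Ratio guards a zero minor axis.
- CSV feature tables round-trip at full float64 precision (the reader uses
  exact round-trip float parsing).
- Determinism: preprocessing, registration, subtraction and segmentation
  are seed-free and bitwise deterministic; every stochastic component
  (generator, ADASYN, tree ensembles, network initialization, fold
  shuffling) takes an explicit seed.

## Known limitations

- The demons flavor is the classic intensity-driven variant; diffeomorphic
  or log-domain variants are out of scope.
- The mRMR estimator uses coarse (16-bin) discretization for pairwise
  mutual information; rankings on near-duplicate features can depend on
  binning.
- Per-fold selection mode omits the two wrapper selectors (SFS/SBS) for
  run-time reasons; they remain available for offline, global selection.
- `fp_per_image` uses images that produced at least one ROI row as its
  denominator (identical to all images on the default cohort).
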