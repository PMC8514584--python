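# Methods

## Problem and model

A cytological specimen yields many microscopy fields per patient, and a
benign/malignant call is available only per patient (case), not per cell.
`admil_cyto` treats this as multiple instance learning (MIL): every field is
tiled into square patches, the retained patches of all of a case's fields
form one *bag*, and classification happens at the bag level under the weak
case label.

Each instance (patch) `I_k` is mapped by a CNN backbone to a feature vector
`h_k` of length `L`.  The bag representation is the attention-weighted
average

    z = Σ_k a_k h_k,
    a_k = softmax_k( wᵀ tanh(V h_k) ),

with trainable `V ∈ R^{D×L}` and `w ∈ R^D`; a single sigmoid neuron on `z`
gives P(malignant).  The weights `a_k` are positive and sum to one per bag,
which yields three checkable invariants: permutation invariance of the bag
probability, `z` inside the coordinatewise convex hull of the `h_k`, and
exact reduction to mean pooling when `w = 0`.  The mean-pool baseline
replaces attention with the unweighted average; the supervised baseline
classifies each patch individually (every patch inherits its case label —
deliberately noisy supervision) and aggregates by the maximum malignancy
probability per image and then per case, mirroring the clinical rule that a
single convincing malignant cell makes the case malignant.

Training minimises binary cross-entropy between the bag probability and the
bag label, one bag per Adam step for the MIL regimes (lr 5e-4, β₁ 0.9,
β₂ 0.999) and batches of 16 patches for the supervised regime (lr 5e-5).
The model kept is the one with the lowest validation loss over the epoch
budget, with last-epoch fallback.  Bag order is reshuffled every epoch from
the run seed; with batch size 1 the ordering is part of the optimisation
path, so seeding it makes runs exactly replayable.

## Numerical core

No deep-learning framework is used: the layer library in `admil_cyto.nn`
implements convolution (im2col lowered to GEMM), max/average/adaptive
pooling, dense layers, inception, residual and dense blocks, and Adam, all
in float32 numpy with hand-derived backward passes.  Every layer's gradient
is verified against central finite differences in the test suite.  Pure
numpy also makes runs bit-reproducible for a fixed seed on a given BLAS.

Five desk-scale backbone families are pinned for reproducibility (the design
families are standard; exact layer counts are this package's choice, sized
for CPU training on 64-px patches):

| name | body | h_k length |
|---|---|---|
| `lenet_like` | 2× (conv5 + maxpool), 20/50 ch | L = 500 (default) |
| `alexnet_like` | 5 conv3 (32/64/96/96/64) + 3 maxpools | " |
| `inception_like` | 2 conv3 + 2 small inception blocks | " |
| `resnet_like` | 3 basic residual blocks | " |
| `densenet_like` | 2 dense blocks (growth 12) + transition | " |

All end with adaptive 4×4 average pooling, so 64/96/128-px patches are
accepted unchanged.  Attention hidden width `D = 128` and `L = 500` follow
the original attention-MIL design.  Patch pixels are scaled to [0, 1]; no
mean/std normalisation.  Decision threshold is 0.5 on the sigmoid output.

## Instance generation

Fields are tiled from the top-left into a non-overlapping grid; partial
right/bottom tiles are dropped (padding would inject synthetic background
into instances).  At the native 1280×960 geometry a 64-px grid divides both
dimensions exactly (300 candidates); at 96 px the remainders are dropped
(130 candidates).  The field is converted to luminance
(Y = 0.299R + 0.587G + 0.114B, rounded half-up) and binarised once per image
with Otsu's method — the threshold `t` maximises between-class variance over
the 256-bin histogram, ties broken toward the lowest level, and pixels
strictly below `t` are foreground, since stained cells are darker than the
illuminated background.  A constant image has no valid split and yields no
instances.  A tile is retained iff its foreground fraction strictly exceeds
`min_cell_fraction` (default 0.10, "more than 10 %").  Retention is
therefore monotone non-increasing in `min_cell_fraction`, which the suite
checks.

## Bags and cross-validation

One bag per case, instances ordered by (image, grid row, grid column);
cases with zero retained patches are excluded with a warning.  Evaluation is
tenfold cross-validation stratified by label and split strictly by case —
never by image or patch — so no test-case pixels can reach training (a
runtime assertion enforces this).  Within each fold, 10 % of the training
cases (stratified, at least one) are held out as validation for model
selection; at very small fold sizes where a stratified draw is infeasible
the draw falls back to a seeded random pick that keeps both labels in
training.  Out-of-fold predictions are concatenated across folds into a
single confusion matrix.

## Metrics

Malignant is the positive class: sensitivity tp/(tp+fn), specificity
tn/(tn+fp), accuracy (tp+tn)/n, balanced accuracy (sens+spec)/2 — the
headline number when class counts are unequal.  Display rounding is half-up
to three decimals; unrounded values are carried internally.  A
`rounded_inputs` mode averages the already-rounded sensitivity and
specificity, which is how printed summary tables are often assembled — one
published balanced-accuracy entry (0.910) is reproducible only this way
(exact: 0.909).  Three published summary entries do not follow from their
own confusion matrices under any standard rounding (a ResNet balanced
accuracy printed 0.900 where the matrix gives 0.895, and a case-based
supervised sensitivity/accuracy printed 0.985/0.849 where the matrix gives
0.986/0.894; the printed "accuracy" there equals the balanced accuracy,
suggesting a transcription slip).  The suite asserts the matrix-derived
values and documents the discrepancies instead of reproducing them.

## Synthetic specimens

The generator emulates Pap-stained brightfield geometry: a bright, faintly
pink background (intensity 230) with elliptical nuclei rendered darker.
Benign-like nuclei: radius 6–10 px, intensity 110–170, near-circular.
Malignant-like nuclei: radius 12–17 px (strictly above the benign range),
intensity 40–90 (strictly darker), higher eccentricity jitter.  Gaussian
pixel noise (sd 8) is added and clipped; images are written as lossless PNG
so fixtures are byte-stable.  In a malignant case every image plants
`max(1, round(0.3 · n_cells))` malignant-like nuclei; benign cases contain
none, so weak labels are exact and each image's tile grid has a ground-truth
malignant/background labelling (a tile is malignant-like iff a planted cell
center falls in it).  The default profile mirrors the native 1280×960
geometry with 40–80 cells per field; the small profile (256×192, 12–20
cells, 2–3 images per case) keeps per-tile cell density comparable and is
what the experiments use.

What passing on this data shows — and does not.  The signal is deliberately
strongly separable (disjoint radius and intensity ranges), so near-perfect
cross-validated accuracy demonstrates that the pipeline (tiling, filtering,
bagging, attention training, fold handling) is wired correctly, not that the
model reaches any particular accuracy on real Pap-stained specimens, whose
nuclei differ in texture, overlap, focus and staining far beyond this model.
Attention localization on planted tiles likewise validates the
weight-to-tile plumbing and the learnability of instance relevance, not
clinical interpretability.

## Experiment sizes

The packaged experiments run tenfold cross-validation on 24 synthetic
small-profile cases (12 benign / 12 malignant, ≈ 10 retained patches per
bag), LeNet-like backbone, 6 epochs, three seed replicates for both MIL
regimes.  These sizes were chosen so a complete replicate set trains in
minutes on one CPU core with the numpy backend; validation loss on this
data plateaus within the first few epochs, so the short budget does not
truncate learning.  The acceptance checks assert balanced accuracy ≥ 0.9
per seed, a positive attention-localization gap, and attention pooling
within 0.05 balanced accuracy of mean pooling.

At 24 cases a single misclassified case moves balanced accuracy by about
0.042, so replicate-to-replicate variation of one or two cases is expected:
across a wider sweep of dataset seeds most replicates score 0.92–1.00 for
both regimes, with occasional harder draws near 0.83.  The 0.05 margin in
the regime-ordering check is therefore at the resolution limit of this
problem size — it tolerates one case of disagreement — which is worth
keeping in mind when running the reproduction script with other seeds.

## Attention maps

For a classified bag, each retained tile is shaded through a blue→yellow→red
colormap (matplotlib `jet` by default; configurable) after normalising
weights by the per-image maximum (default) or the per-bag maximum, and
alpha-blended (α = 0.4) onto the source field; filtered-out tiles stay
unshaded.  Per-image normalisation is the default because a bag maximum on
another image can flatten a single-image display.  Rendering is a pure
function of (image, weights, normalisation), so re-rendering is
byte-identical, and colormap position is monotone in the weight.

## Known limitations

* The numpy backend is single-threaded GEMM-bound; full-scale runs (hundreds
  of cases, 100 epochs, 1280×960 fields) are out of its intended range.
* No batch normalisation in the backbones; very deep variants would need it,
  but the desk-scale depths train fine without.
* The synthetic texture model is intentionally simple (flat-filled ellipses
  plus Gaussian noise); it does not model chromatin texture, nucleoli,
  cytoplasm, cell clusters or focus gradients.
* Supervised-baseline evaluation is per patch, with per-image and per-case
  maxima for aggregation; with sparse disease a case-level max is sensitive
  to a single false-positive patch.
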