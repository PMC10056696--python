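# Methods

This note documents the models and procedures implemented in `medpipe`, the
assumptions behind them, the parameter choices that matter, and what the
synthetic generators do and do not establish about real data.

## Chunked k-means

**Procedure.** Rows are assigned to `n_chunks` chunks by a seeded shuffle of
the row indices split into contiguous blocks; indices are then sorted within
each chunk (this keeps summation order stable and makes a single-chunk run
coincide exactly with plain sequential iteration). Each round, every worker
assigns its chunk to the current *global* centroids and returns per-cluster
intensity sums and counts. The coordinator pools sums and counts and divides
— algebraically identical to count-weighted averaging of the workers' local
centroids, but numerically exact (it avoids the `(c·x)/c` rounding a
centroid-times-count formulation would introduce). The loop stops when the
maximum Euclidean centroid displacement drops strictly below
`shift_threshold`, or after `max_rounds`.

**Design choices.**

- *Workers are pure functions* of (chunk, global centroids). The fit is a
  function of (data, config) only; scheduling and concurrency level cannot
  change the result, which is why the implementation runs workers
  sequentially and still calls itself chunked: the contract, not the thread
  pool, is the point.
- *Convergence direction*: stop when the shift is **below** the threshold.
  (The alternative reading — iterate again when below — does not terminate.)
- *Tie-break*: nearest centroid with the lowest index. *Empty cluster*:
  re-seeded to the point farthest from the cluster's previous centroid.
- *Initialization*: k distinct data rows sampled without replacement under
  the seed.

**Parameters.** `k` (default 2 for tabular data, 5 for images — radiograph
gray levels fall into roughly five bands); `shift_threshold` (default 1e-6,
feature units); `max_rounds` 100; `n_chunks` 1.

**Caveat.** With more than one chunk the merged update is a count-weighted
average of chunk-local statistics, so the trajectory differs from
sequential Lloyd and inertia is not guaranteed monotone round-to-round; on
separated mixtures the fixed points agree to well within 5% inertia, which
the tests assert.

## Tabular preprocessing

Order: mean-impute → min-max normalize → cluster → outlier-flag → augment.
Clustering needs complete, comparably scaled features, which fixes the
order. Missing cells are NaN (CSV: empty or `NA`). Min-max maps each
feature by (x − min)/(max − min); a constant feature maps to 0; the fitted
min/max are retained for application to new data. A row is an outlier iff
its distance to its assigned centroid exceeds the `q`-quantile (default
0.99) of all such distances; flagged rows are dropped by default (a CLI
switch keeps them). Cluster augmentation appends one-hot membership
indicators, or replaces features with the k distances to centroids (a
k-dimensional embedding usable as dimensionality reduction), or both.

## Logistic regression

Full-batch gradient ascent on the Bernoulli log-likelihood with
probabilities clipped to [1e-12, 1 − 1e-12]. Weights start uniform in
[−0.01, 0.01] under the seed. The published gradient is the sum
Σ(yᵢ − f(zᵢ))xᵢⱼ and `gradient()` returns exactly that; the *update* applies
the learning rate to the mean gradient (α·g/n) so step size does not scale
with n. Convergence is declared when the absolute log-likelihood change
falls below `tol`.

`fit_gd` defaults to α = 0.1 (suits standardized or [0, 1] features),
1000 iterations, tol 1e-8. The ensemble pipeline configures its members
with α = 1.0 and 20 000 iterations: on min-max-scaled features first-order
ascent is slow (the curvature is small), and these settings bring the fit
to the same decision function an unregularized reference implementation
reaches, which the tests check. Plain gradient ascent is a deliberate
choice — no second-order steps, no regularization — so the optimizer is
exactly the textbook loop.

## Weighted ensemble

70/30 train/test split (seeded, stratified by default), with a validation
subset (default 20%) carved from the training side. The training remainder
is chunked (seeded shuffle, contiguous blocks, sizes within 1); each chunk
trains one member under a per-member seed derived from the ensemble seed by
stage-name hashing. Member i receives weight ωᵢ proportional to its
validation accuracy (or rank-based AUC), normalized to Σω = 1; all-zero
scores fall back to uniform. Prediction is the convex mixture Σωᵢpᵢ(x),
thresholded at 0.5.

Refinement is a coordinate-wise multiplicative search: each round tries
scaling every weight by 1.1 and 0.9 (renormalizing), accepts the best
strictly improving candidate, and stops on a round with no improvement or
after `refine_rounds` (default 20). Accepted validation scores are logged;
by construction the logged sequence never decreases. The stopping target is
deliberately the no-improvement rule — no fixed performance goal is baked
in. Only data parallelism is implemented; model or hybrid parallelism is
out of scope.

With one chunk the ensemble is exactly one member with weight 1, and
predictions equal that single fit — the degenerate case the tests pin down.

## Evaluation metrics

Precision TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP),
F1 = 2PR/(P+R), accuracy; rank-based (Mann-Whitney) AUC with ties counted
½. A metric with a zero denominator is returned as `None` — an explicit
undefined marker — never silently as 0. Fractions internally; reports can
scale to percent. Wall-clock speed is logged by the CLI per stage but is
never a test surface (it is hardware-bound).

## Image pipeline

Pixel clustering is 1-D k-means over intensities only: the gray-level bands
of radiographs are an intensity phenomenon, so spatial coordinates are
deliberately left out of the feature vector. Initial centroids are sampled
(seeded) from the *distinct* intensity values — sampling rows would allow
two seeds inside one plateau, and plateau images would then fail to
separate; if the image has fewer distinct intensities than k, k is reduced
with a warning. Labels are canonicalized darkest-first (ascending cluster
mean), making them stable across runs.

The rendered "clustered image" replaces each pixel by its cluster mean
(rounded to the image depth), so it has at most k distinct values. Outlier
pixels — deviating from their cluster mean by more than t·σ of the cluster
(default t = 3) — are replaced by the cluster mean. Resizing is bilinear to
`side × side` (default 640) followed by min-max to [0, 1]; a constant image
maps to zeros. Region features per cluster: area, centroid, bounding box,
mean intensity, variance, bbox aspect ratio; areas sum to H·W. The
2-channel stack pairs normalized intensity with labels/(k−1), giving a
detector the pixel-group as an extra feature plane. Pipeline order is
cluster → outlier removal → render → resize/normalize.

Inputs are 8- or 16-bit grayscale PNGs (or arrays); DICOM and 24-bit color
are out of scope.

## Detection geometry

Cells are half-open intervals [i·c, (i+1)·c) with c = image_side/S; a
center on an interior boundary belongs to the higher-index cell, and the
far image edge to the last cell. Box encoding is **cell-relative
throughout**: (bx, by) ∈ [0, 1] are the center offsets inside the owning
cell and (bw, bh) are width/height in units of the cell size. This differs
from the common convention of image-relative widths; `encode_box`/
`decode_box` are exact inverses (round trips hold to 1e-9 px), so
conversion to any other convention is mechanical.

Confidence is the product Pr(class|obj)·Pr(obj)·IoU; at inference the IoU
factor is unknown and treated as 1. NMS is greedy per class: drop
detections below the objectness threshold (default 0.5, the low end of the
usual 0.5-0.7 range), keep the highest-confidence survivor, suppress others
with IoU strictly above the threshold (default 0.5); ties break by
confidence then input index. Anchor priors come from Lloyd iteration over
ground-truth (w, h) pairs with the 1 − IoU distance of co-centered boxes
(the Euclidean chunked path cannot take a custom metric, so this lives
beside it, sharing the seeded initialization); anchors are sorted by area.

The loss matches each truth box to the best-IoU prediction within its
owning cell, then sums MSE over the encoded (bx, by, bw, bh) and mean
cross-entropy of class probabilities against the one-hot truth.

**Backbone contract.** Any callable image → tensor of shape
(S, S, A, 5 + C) with channel layout [pobj, bx, by, bw, bh, class probs].
`detect_and_flag` decodes the tensor, applies NMS, and flags the image
*affected* iff any surviving detection carries the disease class. The grid
defaults (S = 7, 3 anchors, 2 classes) are configuration values, not
claims about any particular dataset.

**Reference backbone.** `TinyLesionBackbone` is a deliberately small
trainable predictor used to exercise the machinery end to end: per-cell
intensity statistics [mean, std, max, bright-fraction] on a fixed [0, 1]
scale feed (a) an objectness head — the package's own logistic regression,
trained 200 steps on a class-balanced cell sample, (b) a least-squares box
regressor on positive cells (log-scale widths keep them positive), and
(c) the empirical class distribution of the training objects. It is a
cell-statistics model, not a convolutional network, and its flag-accuracy
figures are in-sample machinery checks, not generalization claims.

## Synthetic generators

`gen_tabular` draws a k-component Gaussian mixture (unit variance,
component means `separation` σ apart along a random unit direction) and
labels y ~ Bernoulli(f(w₀ + w·x)). Defaults: n = 2000, d = 5, k = 2
components, separation 2σ, w₀ = −1, w = (2, −3, 1.5, −1, 0.5) (cycled to
d), 5% missing cells, 1% outlier rows displaced far along random
directions. Labels are drawn from the clean features *before* corruption is
injected, so the label law stays purely logistic — that is what makes
parameter recovery (L2 error < 0.3 at n = 5000) a meaningful check, and
what makes outliers genuinely harmful rather than informative.

`gen_images` builds `n_bands` = 5 horizontal intensity bands at levels
20..180 (8-bit) plus Gaussian noise (default σ = 2); with probability
`lesion_rate` an image receives 1-3 bright ellipses at level 245 with
recorded bounding boxes. Lesions are brighter than every band by
construction, so they always form their own intensity cluster — this makes
the interaction between k = 5 quantization and lesion visibility testable.

**What passing tests do not show.** The generators reproduce the
*statistical structure the pipeline assumes* (mixture clusters, a logistic
label law, gray-level bands, bright compact lesions), not real clinical
data: no radiographic texture, no patient-level covariate shift, no class
imbalance, no annotation noise, no DICOM metadata. Accuracy figures on
synthetic data are regression anchors for the implementation, not clinical
performance estimates.

## Problem sizes and numerics

Default working sizes are desk-scale by design: 128 px synthetic images
(clinical CT slices are commonly 512 px; the pipeline accepts any size),
grids of S = 7-8, tabular n in the low thousands. Quantile, mean and
resize steps delegate to NumPy/scikit-image; tolerances of note are the
1e-12 weight-sum check on ensemble weights, probability clipping at 1e-12,
the 1e-9 box round-trip bound, and strict-inequality conventions at
thresholds (NMS suppresses IoU *above* the threshold; k-means stops *below*
the shift threshold). All randomness flows from one global seed, expanded
per stage by crc32 stage-name hashing, so adding a stage never perturbs
earlier streams.

## Known limitations

- The chunked merge changes the optimization trajectory versus sequential
  Lloyd for `n_chunks` > 1 (fixed points typically agree; the path does
  not).
- First-order logistic fitting needs many iterations on poorly scaled
  problems; the pipeline mitigates this with its optimizer settings rather
  than a second-order method, which is out of scope.
- The reference backbone detects bright compact lesions only; it has no
  translation-invariant features and no capacity for real radiographs.
- Metrics are binary; multi-class averaging is out of scope.
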