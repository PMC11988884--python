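# Methods

## Problem and model

The task is binary classification of lateral weight-bearing foot
radiographs into *pes planus* (flat foot, calcaneal tilt angle < 18°) and
*not pes planus*. The classifier is a two-stage hybrid:

1. a Vision-Transformer backbone that maps a 224 × 224 RGB image to a
   1000-dimensional feature vector, and
2. an Extreme-Learning-Machine (ELM) head that classifies those features.

Only the head is trained; the backbone is a fixed feature extractor
(pretrained weights can be imported, or random small-variance weights used
for desk-scale work). Features are computed once and cached as arrays —
the backbone is never re-run inside the training loop.

## Backbone

Standard ViT-B/16 geometry: 16 × 16 patches (so a 224 px image yields
14² = 196 patch tokens), linear patch embedding into ℝ⁷⁶⁸, a learned class
token prepended (197 tokens total) and additive learned position
embeddings. Each of the 12 encoder blocks is **pre-norm**:

    x ← x + MHA(LN(x));   x ← x + MLP_GELU(LN(x))

with 12 attention heads (head width 64, scores scaled by 1/√64) and an
MLP expansion ratio of 4. Pooling uses the class token (that is what the
prepended token is for), followed by a final LayerNorm and a linear
768 → 1000 feature head. The 1000-wide head reconciles the encoder's
768-dim class-token output with the fixed 1000-feature interface of the
classifier: it plays the role of a pretrained model's 1000-way
classification layer reused as a feature layer, and is configurable.

Numerical/design choices:

* GELU is the exact erf form; softmax is max-shifted for stability;
  LayerNorm uses ε = 1e-6.
* Preprocessing: bilinear resize to the configured square size, pixel
  scaling to [0, 1], grayscale replicated to 3 channels; the forward pass
  then applies fixed affine normalization (mean 0.5, std 0.5 per channel,
  recorded in the config).
* Patches are ordered row-major from the top-left; each patch flattens as
  (row, column, channel).
* Dropout exists in the block definition but defaults to rate 0; it is
  active only when a rate > 0 **and** an RNG are passed (training mode),
  keeping inference a pure function of (weights, image).
* Random initialization (used for tests and the synthetic benchmark) is
  Gaussian with σ = 0.02, LayerNorm scales 1, biases 0, reproducible from
  a seed. At this variance attention is near-uniform and the residual
  stream keeps the forward map close to linear, which is the intended
  regime for a random (untrained) backbone used as a feature projector.
* Checkpoint interop: weights flatten to a documented name manifest in a
  `.npz`; an adapter also accepts the common ViT-B/16 naming scheme
  (fused qkv, conv-style patch kernel), transposing/reordering to this
  package's conventions. Only synthetic checkpoints are used in tests.

## ELM head

Hidden layer H = g(XW + b) with W ∈ ℝ^(d×L), b ∈ ℝ^L drawn once from
U[−1, 1] and frozen (write-protected arrays; tests checksum them across
training). Activations: sigmoid (default), tanh, relu, gelu. L defaults
to 1000; L = 0 is the documented pass-through (H = X), i.e. the solvers
act directly on the backbone features.

Output weights β ∈ ℝ^(L×2):

* `pinv`: β = H⁺T (minimum-norm least squares via `lstsq`);
* `ridge`: β = (HᵀH + λI)⁻¹HᵀT, λ ≥ 0 (λ = 0 falls back to `pinv`, which
  also covers rank deficiency);
* `adam`: minimizes mean softmax cross-entropy of Hβ against one-hot
  targets plus λ‖β‖² (an MSE objective on the linear outputs is
  selectable). Mini-batches of 16, learning rate 1e-4, β₁ = 0.9,
  β₂ = 0.999, ε = 1e-8, bias-corrected moments, β initialized to zeros so
  runs are deterministic given the shuffling seed. After each epoch the
  validation loss (plain cross-entropy, no penalty) is logged; training
  stops at 250 epochs or after 10 epochs without validation improvement,
  and the best-validation β is returned. The validation split is always
  supplied by the caller (the CV harness passes the held-out fold); the
  solver never re-splits data.

For λ > 0 the objective is strictly convex in β, so the Adam solution is
comparable against an independent convex optimizer; the test suite checks
the optimality gap on a small non-separable instance (a *separable*
instance has its cross-entropy infimum at infinite ‖β‖ and no finite
optimum to compare against).

λ defaults to 1e-4. The class order is fixed as (pes_planus,
not_pes_planus); prediction is argmax of softmax scores with ties
resolved toward the first (positive) class.

## Evaluation protocol

Patient-grouped splitting throughout: a patient's images never straddle a
partition, because two radiographs of the same foot are near-duplicates
and would leak. A fixed test set of patients (default 1/6 of patients) is
removed first; the remaining patients are dealt round-robin into k = 5
folds (sizes within one patient). Per fold: standardize features with the
training folds' mean/std, draw a fresh hidden layer (seed offset by fold
index — "trained from scratch in each fold"), train on the other k − 1
folds with early stopping on the fold itself, and score on the fixed test
set. The degenerate k = 1 plan trains and stops on its single fold.

Metrics are percentages derived from the confusion matrix with pes planus
positive: accuracy, sensitivity (= recall), specificity, precision, F1.
Zero denominators return 0 with a warning. Aggregation is mean and
**population** standard deviation (divisor k) — the convention that
reproduces the reference summary row (e.g. fold accuracies
96.34/98.78/98.78/97.56/98.78 → 98.04 ± 0.976). Published tables truncate
to two decimals and aggregate the truncated values; the acceptance
checks therefore compare full-precision metrics cell-by-cell at ±0.01 and
compute summary standard deviations from the tabulated two-decimal
values. Two kinds of cells in the reference table are internally
inconsistent with their own confusion matrices (two specificity cells and
one F1 cell); the package reproduces the matrix-derived values and the
tests assert the documented disagreement rather than the printed numbers.

ROC and precision-recall curves use an explicit threshold sweep over the
distinct positive-class scores (ties move together), trapezoidal areas,
ROC anchored at (0, 0) and (1, 1). On random instances the ROC AUC equals
the normalized Mann-Whitney U statistic (cross-checked against
scikit-learn in the tests).

## Synthetic data

`render_foot` draws a dim elliptical silhouette plus a bright
heel-to-midfoot band inclined at the requested arch angle, with clipped
Gaussian pixel noise — a deliberately simple parametric stand-in for a
radiograph. The band's slope is the label-bearing signal: a least-squares
fit to the band pixels recovers the generating angle to well under 2°.

`gen_dataset` draws one angle per patient (class chosen by a fair coin,
then angle ~ N(class mean, 3°), means 10° and 26°), derives the label
from the drawn angle against the 18° threshold, and renders each of the
patient's 2 images with an independent 0.5° jitter. Labels are therefore
deterministic in the angle, and all of a patient's images share a label.
The default cohort is 60 patients — a reduced-scale version of a
421-patient / 842-image clinical collection — keeping the full pipeline
in the seconds range.

What the generator does **not** emulate: anatomical variation, exposure
and positioning artifacts, label noise from human readers, and class
imbalance. Passing tests therefore demonstrate that the pipeline's
mechanics (feature extraction, solvers, grouped protocol, metrics) are
correct and that accuracy responds monotonically to class separation —
not that the model reaches any particular accuracy on clinical
radiographs; the ~98% reference accuracy was obtained with pretrained
backbone weights on real data, neither of which ships here.

## Problem sizes

The test suite and acceptance script run the backbone at toy scale
(64 px, 2 blocks, 64 features; one full-geometry 197 × 768 pass is
exercised once) and the synthetic benchmark at 60 patients × 2 images
with a 200-wide head — sizes chosen so the whole suite completes in well
under a minute while still exercising every code path at realistic
shapes.

## Known limitations

* The backbone is inference-only; no gradient path exists through it.
* Binary classification only; the metrics and one-hot encoding assume two
  classes.
* The ViT-B/16 checkpoint adapter is tested against synthetic checkpoints
  only (no pretrained weights are distributed).
* The Adam solver's early-stopping monitor is validation cross-entropy;
  monitoring accuracy instead can pick a different epoch on small folds.
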