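# Methods

## Problem

`gliofuse` predicts MGMT promoter methylation status (a binary label that
conditions temozolomide response in glioblastoma) from multiparametric MRI.
The pipeline follows the transfer-learning route: tumor regions of
co-registered T1, post-contrast T1 (T1wCE), T2 and FLAIR volumes are turned
into short grayscale videos, off-the-shelf video action-recognition networks
supply 400 deep features per modality without any fine-tuning, and a small
trainable classifier fuses the five feature branches (the four modalities
plus the voxelwise T1wCE − T1 "delta" image, which isolates contrast
enhancement).

## Preprocessing

Volumes are assumed co-registered, bias-corrected and skull-stripped
upstream, as in curated public glioma collections. The package then applies,
in this fixed order:

1. **Geometry standardization** — trilinear resampling to 1 mm isotropic
   voxels, then a center crop / zero-pad to 240 × 240 × 150. Masks use
   nearest-neighbour resampling. Crop start is `(in − out) // 2` per axis so
   the input center maps to the output center.
2. **Delta volume** — `T1wCE − T1` computed on standardized, still-raw
   intensities, *before* normalization, so the difference image receives its
   own intensity window (a post-normalization difference would leave the
   8-bit range and lose enhancement contrast).
3. **Intensity normalization** — the 1st–99th percentile window (computed
   globally over all voxels, linear-interpolation percentile definition)
   maps linearly to 0–255; values beyond the window saturate; rounding is
   half-away-from-zero. A constant volume (p99 == p1) yields all zeros with
   a warning rather than aborting a cohort run.
4. **Bounding box** — a fixed 128 × 128 window anchored at the tumor's
   minimum row and minimum column over *all* slices, shared by every frame.
   If anchor + 128 overruns the image the corner is clamped to
   `dim − 128` (anchor-and-clamp: a tumor wider than the window is truncated
   on the far side). Coordinates are 0-based; rows index the image's
   vertical axis, columns the horizontal one.
5. **Video conversion** — axial slice *k* becomes frame *k*; every subject
   yields exactly five 150 × 128 × 128 8-bit clips.

## Feature extraction

The extractor contract is `clip → 400 finite floats`, pure in the clip
content. Adapters for pre-trained networks (I3D, SlowFast, IRCSN, ViViT —
all Kinetics-400 checkpoints) plug in behind this contract but are optional:
nothing in the package or its tests downloads weights. The built-in
`StubExtractor` is a deterministic extractor used throughout the test suite:
the clip is partitioned into 6 × 4 × 4 blocks, each contributing its mean,
variance and mean absolute frame-to-frame difference; the 288 moments pass
through a projection matrix and bias drawn once from a pinned seed. Distinct
clips map to distinct vectors, the zero clip maps exactly to the bias
vector, and output is identical across platforms. It is a test fixture with
a closed form, not an approximation of any pre-trained network.

## The fusion classifier

Per subject the input is a 5 × 400 matrix (branch order FLAIR, T1, T2,
T1wCE, delta-T1). Features are z-scored per branch-feature with statistics
fit on the training fold only, then pass a univariate screening gate: a
feature is kept only when the class-mean difference on the training fold
exceeds `screen_z` (default 3) standard errors. Screening is the classical
radiomics feature-selection step, and it matters here for a statistical
reason: a dense network under weight decay behaves like a ridge model,
whose attainable AUC in this regime is limited by the ratio of feature
count to sample size regardless of how concentrated the signal is; the
screen restores the sparse-estimation rate. The gate is part of the fitted
model (leak-free under cross-validation) and `screen_z=0` disables it.

- **Shared (Siamese) encoder**: one dense stack 400 → 128 (ReLU, dropout
  0.3) → 64, applied identically to all five branches. The sharing is by
  parameter identity — a single tensor set — not tied copies.
- **Attention**: branch scores `s_b = u · tanh(W e_b + c) + γ β_b` where
  `e_b` is the branch embedding, `β` a learned per-branch bias (a branch
  embedding for the scorer, analogous to a positional embedding) and
  γ = 30 a fixed gain. `α = softmax(s)` gives nonnegative per-subject
  weights summing to 1. Three choices matter and were made deliberately:
  - *The bias term is necessary.* With a strict Siamese encoder and a
    branch-symmetric scorer the architecture is exchangeable across
    branches; the mean attention profile could then differ across
    modalities only through content statistics, for which the gradient is
    very weak, and attention stays near-uniform — diluting a
    single-modality signal by the branch count. The bias accumulates
    preference evidence across all subjects and lets attention concentrate.
  - *The bias is warm-started from per-branch linear probes.* Learning the
    branch preference from scratch inside a softmax is fragile: an early
    commitment to the wrong branch starves the informative branch of
    gradient (winner-take-all lock-in) and cannot recover. Before training,
    a split-half ridge-logistic probe measures each branch's marginal AUC
    on the training fold; `β` is initialized to
    `probe_gain · (AUC_b − 0.5) / γ` (probe_gain 10) and remains fully
    learnable. On a cohort with no informative branch the probes hover at
    0.5 and the initialization is near-uniform.
  - *The content scorer starts silent* (`u = 0` at init) so the
    per-subject content term grows only as the gradient supports it.
- **Fusion and head**: `fused = Σ_b α_b e_b`, then a linear layer and
  sigmoid give P(methylated).
- **Missing modalities**: an absent branch's score is masked to −∞ before
  the softmax, which is exactly a renormalization of the remaining weights;
  the fused vector then uses present branches only. No retraining is needed
  for inference-time missingness (the retrained-without-branch variant is
  available in the ablation module).

### Training

Adam (lr 1e-3, batch 32) with decoupled weight decay 10 on weight matrices
(biases, the attention bias β and the scorer vector u are not decayed),
binary cross-entropy loss, at most 200 epochs. Early stopping monitors the
AUC of an inner stratified 10% validation split with patience 20, with a
100-epoch burn-in during which neither stopping nor best-epoch snapshots
occur: the inner split is small (≈50 subjects at the default cohort size),
its epoch-level AUC is noisy, and without the burn-in a lucky early peak
regularly ends training — or worse, gets its weights selected — long
before the attention weights converge. Best post-burn-in epoch weights are
kept.

Because the loss surface is non-convex and a single run can settle in a
poor basin (in particular with attention locked onto uninformative
branches), `fit` trains `n_restarts = 3` members, each with its own inner
split, initialization and batch stream, and predicts with the average of
the member probabilities (a restart ensemble). Attention weights are
member-averaged, which preserves nonnegativity and the sum-to-one
constraint. With `n_restarts=1` the estimator reduces to a single
early-stopped network. Everything is bit-reproducible given
`random_state` in single-threaded NumPy.

The strong weight decay deserves a note: with 400-dimensional branch inputs
and a few hundred training subjects the network can memorize the training
set within a handful of epochs, after which no useful gradient remains.
Decay of this magnitude keeps the effective capacity near that of a
regularized linear model while the attention mechanism learns which branch
to trust; together with the screening gate this combination approaches the
sparse-estimation ceiling of the informative branch on the synthetic
cohorts.

The MLP baseline (400 → 100 → 32 → 1, dropout 0.4, T1wCE branch only)
trains under the same loop with weight decay 30 and a 60-epoch burn-in.

Both models are implemented directly in NumPy (dense layers, softmax
attention, Adam, backprop verified against finite differences in the test
suite); at these sizes a fold trains in seconds on one CPU core.

## Evaluation protocol

- 4 repetitions of stratified 5-fold CV → 20 fold-level values per metric;
  reported as mean ± SEM with SEM = sd(n−1)/√20. Stratification is used
  because ablation cohorts can be imbalanced; the plan (and its SHA-256
  hash) make paired comparisons explicit.
- AUC via the Mann–Whitney pair-counting definition (delegated to
  scikit-learn; an independent brute-force pair counter is the test
  oracle). Precision/recall/accuracy at threshold 0.5; a fold with no
  predicted positives reports precision as missing and is excluded from the
  precision average with a warning.
- Wilcoxon rank-sum on fold-metric vectors: midranks for ties; exact null
  by full enumeration when C(n+m, min(n,m)) ≤ 2·10⁵ (handles ties exactly),
  scipy's exact recursion for larger tie-free cases with n·m ≤ 400,
  tie-corrected normal approximation otherwise.
- Decision-curve analysis: net benefit `TP/n − (FP/n)·t/(1−t)` on a
  0.01–0.99 grid (step 0.01), against treat-all and treat-none policies.
- External validation reuses the per-fold internally trained models on the
  external cohort without refitting.
- Lin's concordance correlation coefficient (population 1/n moments):
  `2·cov / (var_x + var_y + (mean_x − mean_y)²)`, per feature column across
  subjects, for cross-extractor reproducibility.

## Synthetic data

Two generators make every stage testable without downloads.

**Phantoms** emulate a curated scan: homogeneous background intensity 100,
an ellipsoidal tumor `{x : Σ((x_i−c_i)/r_i)² ≤ 1}` with per-modality
tumor-to-background contrast (defaults 0.8, 1.6, 1.3, 1.4 for T1, T1wCE,
T2, FLAIR — T1 hypointense, T1wCE strongly enhancing so the delta image
carries signal), plus N(0, σ²) noise (default σ = 2 intensity units). They
do *not* model MR physics, bias fields, texture or irregular tumor shapes;
they exist to pin the geometry/intensity contracts of preprocessing.

**Feature cohorts** draw labels Bernoulli(prevalence) and independent
unit-variance Gaussian features; class 1 adds a mean shift spread over the
informative features of each branch so the between-class Mahalanobis
distance per branch equals the configured effect size. This makes the
Bayes-optimal AUC of a single informative branch exactly Φ(Δ/√2) — the
closed form that anchors the recovery tests (Δ = 1.5 → 0.8556). Defaults:
585 subjects and prevalence 0.5 for the internal cohort, 81 subjects and
prevalence 0.75 methylated for the external preset (the external cohort in
this problem domain is ~75% methylated; the internal split is described
only as roughly balanced, so 0.5 is a neutral default, not a literature
value).

`informative_fraction` defaults to 0.025: 10 of 400 features carry the
shift per branch, mirroring the small signatures typical of radiomics
panels. The concentration is a statistical requirement of the recovery
design, not a stylistic choice: a learner can only approach the Φ(Δ/√2)
bound when the informative features are individually detectable on a
training fold. With k informative features the per-feature shift is Δ/√k
and its detection z-statistic at n ≈ 470 is about 2.3·Δ/√k; at k = 40 that
is ≈ 2.6 (selection is unreliable and even an oracle-thresholded linear
model plateaus ~0.08 below the bound), while at k = 10 it is ≈ 5 and
selection is essentially perfect. One global seed fans out to per-subject
substreams, so subject *i* is identical regardless of cohort size.

Paired extractor tables for the CCC study draw each feature column from a
bivariate normal with equal moments and correlation ρ; with equal marginal
moments the population CCC equals ρ exactly, so the requested concordance
is analytically verifiable. The sample CCC at ρ = ±1 differs from ±1 by the
squared sample-mean term, O(1/n).

What passing on these cohorts shows — and does not show: recovery of a
known separable signal, correct attention identification, graceful
missing-modality degradation and correct bookkeeping are all verified; the
generators are deliberately simple (no feature correlations, no batch
effects, no site heterogeneity), so absolute performance numbers on real
imaging cohorts are not implied.

## Numerical choices and degenerate inputs

- Percentile definition: NumPy linear interpolation; rounding
  half-away-from-zero (pinned for bit-reproducibility).
- Constant volumes normalize to zeros with a warning; empty masks, single-
  class training sets, all-absent branch masks, and extractors emitting the
  wrong dimension raise errors.
- CCC of two identical constant vectors is 1 (0/0 resolved by continuity);
  Pearson on constant input is an error.
- Attention softmax masking uses −1e30 rather than −inf to avoid NaNs.
- Training arithmetic runs in float32 (parameters, activations, optimizer
  state) for speed; converged members are stored and evaluated in float64,
  so inference-side contracts (attention sums, probability symmetry) hold
  to full double precision. Both phases are bit-deterministic given the
  seed in single-threaded NumPy.
- Early-stopping ties favor the earlier epoch (strict improvement by
  >1e-12 required).
- Fold-level model seeds are derived from the split-plan seed, so a CV run
  is a pure function of (cohort, plan, estimator config).

## Problem sizes

Default test and acceptance runs use the full 585-subject internal cohort
with 4×5-fold CV for the fusion and baseline models, an 81-subject external
cohort, and 400-feature tables for concordance studies; ablation grids in
the unit suite run on 100-subject, 30-feature cohorts with single-repetition
5-fold plans, which is sufficient to exercise the paired design.

## Known limitations

- The restart ensemble triples training cost; with one restart the variance
  across seeds is noticeably larger.
- The attention bias gain γ and weight decay were chosen for 400-feature
  branches at cohort sizes of a few hundred; very different regimes will
  need retuning.
- Inference-time masking and retrained leave-one-out models answer related
  but different questions; the ablation module reports both.
- The stub extractor is injective on realistic clips but not provably so
  for adversarial pairs agreeing on all block moments.
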