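# Methods

## Problem and model

`connectopred` predicts 2-year cognitive outcome in very preterm infants
from the term-equivalent-age structural connectome: a 90×90 symmetric
adjacency matrix whose edge (i, j) is the mean fractional anisotropy (FA)
of the white-matter tract between atlas regions i and j.  Outcomes are
Bayley-III-style cognitive scores (scale 40–160, population mean 100,
SD 15); a score below 90 defines the high-risk class, so a typical cohort
is imbalanced (~25% high risk).

The primary model (TL-CNN) treats the adjacency matrix as a 2-D image and
applies transfer learning:

1. **Frozen backbone.** The convolution/pooling stack of VGG19 — 16
   convolutional layers (3×3 kernels, ReLU; widths 64,64,128,128,256×4,
   512×8) with five 2×2/stride-2 max-pool stages.  On a 90×90 input the
   spatial size follows floor-halving 90→45→22→11→5→2, so the output is a
   2×2×512 feature map.  Backbone parameters are excluded from every
   gradient update.
2. **Trainable shallow head.** Two 3×3 same-padding convolutions of 256
   filters on the 2×2 grid, then fully connected layers of 256 and 64
   units, each followed by batch normalization and dropout, and a task
   output: a two-way softmax (classification, cross-entropy loss
   J(W,b) = −(1/N) Σ yᵢ log p(xᵢ) + (1−yᵢ) log(1−p(xᵢ))) or a single
   linear unit (regression, MAE loss L(W,b) = (1/N) Σ |yᵢ − ŷᵢ|).
   Training uses Adam with learning rate 0.001 for 50 epochs; when a
   validation split is available the epoch with the lowest validation
   loss is kept.

Because no deep-learning framework is part of the dependency set, the
network stack (convolution via im2col/GEMM, max-pooling, batch-norm,
dropout, Adam, backpropagation, Grad-CAM) is implemented directly on
NumPy in `connectopred.nn`; analytic gradients are verified against
central finite differences in the test suite.

### Backbone weights

Externally supplied pretrained weights can be loaded from an `.npz` file
(`conv{i}_weight`/`conv{i}_bias`).  When no file is given the backbone is
built with a deterministic He-normal random initialization of the same
architecture, still frozen.  Every pipeline contract (frozen-parameter
conservation, feature shapes, training, saliency) is exercised offline in
this mode, but the transfer-learning *benefit* of ImageNet features is
then absent — see *Limitations*.

### Input adaptation

The backbone is a 3-channel colour-image architecture; a connectome has
one channel.  `adapt_input` replicates the matrix onto all three channels
and (in random-init mode) standardizes each matrix to zero mean and unit
variance over its own entries.  Per-matrix standardization is leakage-free
and keeps the mapping a pure function of the matrix, which lets the frozen
backbone cache features content-addressed — identical subjects recurring
across folds and repeats cost one forward pass in total.  For pretrained
weight files the raw [0, 1] FA scale is kept (`mode="unit"`).

Regression targets are standardized internally with fit-set mean/SD and
predictions mapped back to score units (Adam at learning rate 0.001 could
not traverse the ~100-point offset in 50 epochs otherwise); the recorded
MAE history is rescaled to score units.

## Data augmentation

Score-binned convex-combination oversampling (a SMOTE variant for
continuous labels): training subjects are binned at score thresholds
70/80/90/100 (left-closed intervals); bins are visited round-robin
(empty bins skipped); a base sample is drawn uniformly from the bin, its
k = 5 nearest neighbours (Euclidean distance on the 4005-dimensional edge
vector) are found — within the bin when it has ≥ k+1 members, else over
the whole training set — and a synthetic sample is the convex combination
of the k+1 connectomes and scores under weights drawn uniformly on the
simplex.  Originals are retained; sampling stops when the set reaches
`expansion_factor` (default 10) times its original size.

Two interpretation choices are deliberate: bases and neighbours are drawn
from the *original* training samples only, so every synthetic subject
carries an exact contributor-id list (the leakage audit depends on it);
and augmentation is fitted and applied strictly inside the
cross-validation fit portion — applying it before splitting would place
convex copies of test subjects in the training set.

## Evaluation protocol

Five-fold cross-validation, stratified by risk label (at n≈80 with ~25%
prevalence an unstratified fold can lack a class entirely), with the
non-test portion split 70/30 into fit and validation sets; the validation
set drives epoch selection (networks) and hyperparameter grids
(logistic/ridge: 10⁻³…10¹; SVM soft margin: 2⁻³…2³).  The whole procedure
is repeated with fresh splits (50 repeats in the published protocol) and
per-repeat metrics are computed on the pooled test-fold predictions:
sensitivity/specificity of the high-risk class at probability threshold
0.5, balanced accuracy, and AUC for classification; Pearson r, MAE, and
the SD of absolute errors for regression.  Summaries report the mean and
the percentile (2.5th, 97.5th) interval across repeats.  Note that this
interval describes the dispersion of per-repeat estimates: its width
*grows* (toward the population interquantile range) as repeats increase,
which is the property the test suite checks.

A robustness experiment applies one random region permutation identically
to rows and columns of every matrix (scores unchanged).  Edge-identity-
tracked quantities (e.g. edge–outcome correlations) are invariant under
the relabelling; the learned spatial prior of the CNN is not.

## Grad-CAM edge importance

For a trained TL-CNN, saliency is computed at the last convolutional
layer of the network (the second head convolution, spatial size 2×2):
channel weights are the spatial mean of the target-output gradient (the
high-risk logit, or the linear output for regression), the weighted
activation sum is rectified, bilinearly upsampled to 90×90, symmetrized
and zero-diagonalized.  Per-subject maps are min-max normalized before
averaging (raw Grad-CAM magnitudes are not comparable across subjects);
the aggregated map yields the top-k edge ranking with atlas names, ties
broken lexicographically by region index.

This map is intrinsically coarse: before upsampling it has 2×2 = 4
spatial degrees of freedom, each unit's receptive field spans the whole
90×90 matrix, and bilinear upsampling adds no information.  Edge-level
localization claims from such maps should be read accordingly — see
*Limitations*.

## Synthetic cohorts

The generator emulates the statistical skeleton the method assumes, not
diffusion imaging itself.  Scores are drawn Normal(100, 15) and clamped
to [40, 160] (high-risk prevalence ≈ Φ(−2/3) ≈ 0.252); clamping happens
before the standardized score z is computed so labels and planted effects
agree with stored scores.  Connectomes are a baseline FA pattern
(constant 0.4 by default; a structured 90×90 baseline may be supplied)
plus i.i.d. Gaussian edge noise (SD 0.02 by default — the scale of
inter-subject tract-FA variability), with selected "effect" edges set to
baseline + α·s·z + noise, where s = 0.1 FA units per score SD and
α ∈ [−1, 1] is the planted strength.  Matrices are clipped to [0.05,
0.95] and symmetrized; everything is byte-reproducible from one seed.
A source-domain pool for unsupervised pretraining uses a shifted baseline
(0.45, noise SD 0.03) as a distribution-level domain gap, with scores
flagged unused.

What the generator does **not** emulate: spatially structured FA (block
structure of lobes), scanner/batch effects, tract-length or density
confounds, heteroscedastic noise, or correlated edges.  Passing tests
therefore demonstrate pipeline correctness and recoverability of planted
linear effects, not clinical performance.

## Comparison models

Logistic regression / ridge regression and SVMs (linear, polynomial,
RBF; γ = "scale") operate on the standardized 4005-edge vectors through
scikit-learn with the published grids.  The printed regularization values
10⁻³…10¹ are used directly as scikit-learn's C (logistic) and alpha
(ridge).  The DNN baseline is a 4005→256→64 fully connected network with
batch-norm and dropout; the TL-DNN is the same network whose encoder
layers are initialized by tied-weight autoencoder pretraining (MSE
reconstruction of standardized edge vectors, 4005→256→64→256→4005,
decoder weights shared transposed) on a source cohort.  The from-scratch
CNN baseline uses two 3×3 convolutions of 256 filters on the 90×90
matrix; a 4×4 max-pool follows each convolution (90→22→5) because a
stride-1 256-channel stack would otherwise flatten to ~2 million
features (~5·10⁸ FC parameters) — no downsampling scheme is part of the
published description, so this is the package's own choice.

## Numerical and design choices

- Connectome symmetrization tolerance 1e-9 (absorbs round-trip float
  noise; larger asymmetry is a format error naming the offending cell).
- Edge order: upper triangle, row-major, i<j, 0-based; one convention
  package-wide.
- Probabilities are clipped at ε = 1e-7 inside the cross-entropy.
- Dropout rate 0.5, batch size 16 (conventional; not fixed by the
  published description; exposed in the configs).
- MAE's subgradient at zero residual is taken as 0 (`np.sign`).
- Batch-norm: momentum 0.9 running statistics; inference-mode backward
  treats μ/σ as constants (used by Grad-CAM).
- Tie-breaks: neighbour search resolves equal distances by subject index
  (stable argsort); edge rankings by (min index, max index).
- Per-stage seeds in the pipeline are derived as
  SHA-256(global_seed:stage) mod 2³¹.

## Problem sizes in the test suite

The published protocol (5-fold × 50 repeats, 10× augmentation, 50
epochs) is implemented in full and configurable, but the bundled
experiments run at reduced sizes chosen for a single CPU: the learning
recovery experiment uses n = 300 subjects with three planted edges
(|α| = 0.8) and one cross-validation repeat against a label-permuted
control on the same connectomes; the saliency recovery experiment uses
three generator seeds at n = 120 with a single 70/30 split; the
generator calibration check uses n = 10,000.  `scripts/acceptance.py`
reports the calibration quantities at n = 10,000.

## Limitations

- **Random-init transfer mode.**  Without an external pretrained weight
  file the frozen backbone is a random (He-normal) feature extractor.
  Random convolutions mix the handful of informative matrix entries into
  all 2048 output features, so the sparse-recovery advantage a classifier
  has in edge space is lost; on the package's separable synthetic cohorts
  a tuned linear probe on these features plateaus near 0.70 balanced
  accuracy while a sparse model in edge space approaches the cohort's
  Bayes level (~0.93).  The random-init mode validates every pipeline
  contract but not the performance benefit of transfer learning.
- **Grad-CAM resolution.**  A 2×2 class-activation grid cannot single
  out individual edges among 4005; aggregated rankings localize at the
  quadrant scale at best (planted-edge median ranks on synthetic cohorts
  are in the upper hundreds to low thousands, not the top tens).
- The head's ~7·10⁵ parameters against tens of training subjects overfit
  quickly; epoch selection and augmentation mitigate but do not remove
  this at desk scale.
- **Oversampling at p ≫ n with sparse planted signal.**  Synthetic
  subjects share their contributors' noise realizations, so a
  high-capacity classifier can separate an augmented training set
  perfectly by memorizing contributor noise fingerprints without using
  the planted edges; on these synthetic cohorts the oversampling
  rebalances classes but does not improve held-out discrimination.
  Real connectomes, whose outcome signal is distributed over many edges,
  are the regime the technique was designed for.
- With ~25% high-risk prevalence, a fixed 0.5 probability threshold can
  leave sensitivity near zero even when AUC shows clear ranking signal;
  balanced accuracy at that threshold should be read together with AUC.
- Lobe labels for atlas indices 29–36 are not part of the published
  grouping and are reported as `unlisted` rather than guessed.
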