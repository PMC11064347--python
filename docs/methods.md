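# Methods

## Problem setting

`latemix` predicts 1-sd classes of five continuous cardiovascular risk
factors — systolic and diastolic blood pressure (SBP, DBP, mmHg) and three
echocardiographic markers of left-ventricular diastolic dysfunction (E/e'
ratio, E/A ratio, LAVI in mL/m²) — from three blood-derived omic blocks:
transcriptomic intensities (thousands of features), metabolomic
concentrations (hundreds) and methylation beta values in (0,1) (tens, a
literature-curated CpG panel). A sample is labelled −1/0/+1 per target
according to whether its raw value lies below, within or above one training
standard deviation of the training mean; under an approximately Gaussian
target this yields a ~15/70/15 class split, so macro-F1 (the unweighted mean
of the three class F1 scores) is the headline metric — a
prevalence-proportional random predictor scores exactly 1/3 regardless of
the imbalance.

## Preprocessing

Targets are adjusted for age, sex and BMI by OLS residualization
(coefficients fitted on training samples only) and z-scored by training
residual moments; the adjusted matrix **Y** supervises the autoencoders,
while classing always uses the *unadjusted* targets. Transcripts are kept
when nominally correlated (two-sided Pearson nullity test, p < 0.05) with
adjusted SBP or DBP, or with any adjusted LVDD marker while exceeding a raw
training variance of 0.01; no multiplicity correction is applied, matching
the per-feature screening the pipeline mimics. Methylation features come
from a user-supplied id list and bypass scaling (beta values are retained as
such). Transcriptomic blocks are min-max scaled and metabolomic blocks
z-scored, always with statistics frozen on the training samples; test values
may leave [0,1] and are not clipped. Every fitted preprocessing artifact
records a provenance hash of the exact training sample ids, and the pipeline
re-verifies these records on every run, so leakage of validation or test
information into any statistic is a hard error, not a convention.

Boundary conventions: a value exactly at mean ± sd falls in the mid class
(the deviant classes require strict exceedance); ties in predicted
probabilities resolve toward the mid class, then the low class.

## Semi-supervised autoencoder

Per continuous omic block the encoder is input → dense(p, LeakyReLU) →
dense(l, LeakyReLU); the decoder mirrors it with a linear output; a
one-layer perceptron head (dense(l, LeakyReLU) → dense(t, linear)) grafted
on the bottleneck predicts the t = 5 adjusted targets. The loss is the
convex bi-output objective

    L = alpha * MSE(X, X') + (1 - alpha) * MSE(Y, Y'),

where X' reconstructs the *original* data from a Gaussian-corrupted input
(denoising; fresh noise each epoch, sd 0.01 for min-max-scaled
transcriptomic data and 0.1 for z-scored metabolomic data, roughly a tenth
of a feature sd in both cases) and each MSE is a mean over all matrix
elements, which keeps the reconstruction caps below comparable across block
widths. `alpha = 1` detaches the head and recovers the unsupervised control
(USAE). Dropout acts on the input layer only, during training only.

Training is mini-batch Adam (batch 64, lr 1e-3, β₁ = 0.9, β₂ = 0.999) with
a per-epoch multiplicative learning-rate decay of 0.9; training stops after
a minimum epoch count once the validation loss fails to improve on its
moving average over the trailing window (min-epochs/window 10/10 for
transcriptomic, 6/6 for metabolomic data). One fifth of the model-fitting
partition is held out as the validation sample. Architecture selection
trains a (p, l) grid and returns the fewest-parameter candidate whose
validation reconstruction MSE is under the per-omic cap (0.015
transcriptomic, 0.25 metabolomic) and whose mean absolute off-diagonal
correlation among bottleneck components stays under 0.4 / 0.3; ties break
toward smaller l, then p. Reference defaults for full-width blocks are
p = 150, l = 50 (transcriptomic), p = 55, l = 6 (metabolomic), alpha = 0.9,
dropout 0.5.

The matched-MSE control trains the USAE until its validation reconstruction
MSE first reaches the paired SSAE's, so both encoders reconstruct equally
well and any downstream difference is attributable to the supervision term.
The pipeline pairs the two runs on the same seed (same initialisation,
batching and corruption draws), which makes the stopping target reliably
reachable; an unreachable target within the epoch budget is an explicit
error.

All networks (SSAE/USAE, VCDN, transfer heads) are implemented directly on
NumPy with explicit backpropagation and an Adam optimiser; at these model
sizes (10²–10⁵ weights) single-CPU training takes seconds, and the
implementation keeps every architectural and numerical choice visible.

## Variable importance

Olden's Connection-Weights importance is the product of the encoder and
head weight matrices, RI = W1·W2·H1·H2 (biases excluded, activations
ignored), preserving sign. With linear activations this equals the exact
input→output Jacobian, which bounds the interpretation of the nonlinear
case; tests verify the identity by finite differences. Importance is
reported raw, z-scored within target across features (population moments),
and as top-percentile ranks of |RI| with mid-rank ties.

## Classification and late integration

Each encoded subspace (or the selected CpG block) is z-scored on training
statistics, joined with age/sex/BMI, and fed to six classifier families —
random forest, linear and RBF SVM (probabilities via sigmoid calibration),
LDA, gradient boosting, one-hidden-layer MLP — through scikit-learn behind a
uniform contract: stratified 5-fold cross-validated grid search selecting on
macro-F1, refit on the full training sample, with out-of-fold probabilities
retained. The tuning grids are deliberately small; the harness, probability
plumbing and leakage accounting are the point, not search breadth.

Fusion builds, per sample, the Cross-omics Discovery Tensor: all c^m
products of the per-omic class probabilities (27 entries for three omics and
three classes), flattened with the first omic's class index most
significant, and rescaled by c^m so a uniform tensor has unit entries (the
rescaling is a design choice that keeps early gradients well-scaled; the
pre-rescale entries provably sum to 1). One View Correlation Discovery
Network per (target, classifier family) — 27 → 9 (LeakyReLU) → 3, softmax
output, cross-entropy, Adam — is trained on *out-of-fold* training
probabilities so the meta-learner never sees in-sample classifier fit, and
evaluated on test-sample probabilities.

## Transfer learning

Hypertension in the external cohort is defined as SBP > 140 mmHg OR
DBP > 90 mmHg (strict exceedance; the conjunctive rule is available via
configuration but contradicts the standard 140/90 usage and the external
cohort's high prevalence). The transfer model inherits the pre-trained
encoder frozen, standardises its bottleneck output on the fine-tuning
samples (the inherited representation has arbitrary scale; treating the
affine correction as part of the frozen feature map lets the new layers
start from unit-scale inputs), then adds dropout, a task hidden layer
(width defaulting to the bottleneck width), concatenation with age/sex/BMI
and a logistic output trained with binary cross-entropy. The from-scratch
clone shares the topology with all layers trainable from random
initialisation. Within a repeat both models see identical fine-tune/
evaluation splits, seeds and batch orders; evaluation is the rank-based
(Mann–Whitney) AUC with ties counted one half. The external block is
preprocessed with its own scaling statistics — base-cohort statistics are
never reused.

## Synthetic cohort generator

Because the underlying study cohorts are access-restricted, the generator
provides the statistical structure the methods rely on and nothing more: a
linear-Gaussian latent-factor model in which a handful of shared factors
drive a sparse subset of features per block and, together with covariate
effects (age, sex, BMI) and Gaussian noise, the five targets. Methylation
values are an inverse-logit squash of the Gaussian score, guaranteeing
(0,1) support. Defaults mirror the study conditions: 1,249 samples (~80%
for model fitting, a fifth of that flagged validation), block widths
2000/200/75 as a desk-scale echo of 5,842/228/75, targets with realistic
means and sds (e.g. SBP 119 ± ~14 mmHg) whose Gaussianity yields the
~15/70/15 class split. The external cohort shares the generative loadings,
is 20 years older, has SBP/DBP offset upward, is enriched for hypertensive
samples by weighted resampling, and receives per-feature additive and
strictly-positive multiplicative batch effects. Not modelled: twin-pair
dependence, missing data, medication adjustment, and any nonlinear
feature–target structure — so green tests certify the pipeline's mechanics
and its directional claims under the planted model, not performance on real
omics.

## Benchmark studies (desk scale)

Three studies reproduce the method's directional findings at sizes chosen
for single-CPU runs of a few minutes:

- **Semi-supervision benefit**: 20 replicates of a 400 × 40 block with two
  dominant nuisance factors and one weaker target factor, bottleneck width
  2. Pure reconstruction fills the bottleneck with nuisance directions, so
  the matched USAE always reaches the SSAE's (slightly worse)
  reconstruction MSE, while supervision pulls the target factor in;
  downstream LDA macro-F1 from the SSAE subspace is at least the USAE's in
  a clear majority of replicates.
- **Late-integration benefit**: 20 replicates of three views, each
  informative about exactly one class; VCDN fusion of per-view LDA
  probabilities beats the best single view in essentially all replicates.
- **Transfer benefit**: 5 meta-replicates of a 700-sample base cohort with
  a wide (600-feature), noisy transcriptomic block — individual features
  too weak for a 62–248-sample from-scratch fit, forcing the value of the
  pre-trained representation — and a 310-sample external cohort.
  Median AUC of the transfer model exceeds the scratch clone's at every
  fine-tuning fraction (20/40/60/80%), with median gains around 0.05–0.25
  and medians increasing with the fine-tuning fraction.

## Known limitations

- The generator's linear-Gaussian structure favours linear learners; LDA is
  used in the benchmark studies for speed, and absolute macro-F1 values are
  not comparable to real-cohort figures.
- The Olden product ignores activations; for strongly nonlinear encoders
  the ranking is an approximation (bounded by the linear-case Jacobian
  identity).
- Per-epoch learning-rate decay of 0.9 effectively freezes training after
  ~50 epochs; studies that need longer optimisation use a slower decay
  explicitly rather than silently training past the schedule's reach.
- The SVM probability calibration (sigmoid, internal CV) is one of several
  defensible conventions; rows are renormalised to the simplex either way.
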