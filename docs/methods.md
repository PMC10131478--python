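# Methods

## Model and training procedure

The classifier is a fully connected network over preprocessed beta values:
two ELU hidden layers (default widths 1000 and 500) followed by a linear
map to C subtype logits and a softmax. The published architecture
description leaves ambiguous whether the pre-softmax activations pass
through the ELU; we use a linear output layer, the standard choice for a
softmax classifier, since an ELU there would bound logits below at −1 and
cap the expressible confidence.

Training runs in two phases, both with Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8; optimizer state reset between phases), dropout on the hidden
activations, and an L2 penalty on weight matrices (never biases):

1. **Pre-training** — cross-entropy over the labeled cohort; defaults
   lr 1e−5, 1500 epochs.
2. **Fine-tuning** — the labeled term plus α(t) times the mean
   cross-entropy of the unlabeled samples against their pseudo-labels;
   defaults lr 1e−3, 3000 epochs.

Pseudo-labels are **hard** argmax assignments, computed in inference mode
(no dropout) so the targets are stable, and recomputed from the current
parameters before every weight update. Training is full-batch by default,
which makes "epoch" and "update" coincide — the natural reading of a ramp
indexed by epoch. With `batch_size` set, pseudo-labels are refreshed
before every batch step while α(t) advances once per epoch. The ramp

α(t) = 0 (t < T₁), α_f·(t−T₁)/(T₂−T₁) (T₁ ≤ t < T₂), α_f (t ≥ T₂)

runs on the fine-tuning epoch clock starting at 0: T₂ = 200 is far below
the 3000-epoch fine-tuning budget and only makes sense on that clock.

With a confidence threshold τ, a pseudo-labeled sample joins the unlabeled
term only while its maximum posterior **strictly** exceeds τ, and the
unlabeled mean divides by the number of admitted samples rather than the
cohort size, keeping the term a proper mean of its contributors. Masks
are recomputed at every update, so early-excluded samples re-enter as soon
as the model becomes confident about them — empirically all samples are
recovered late in training. The threshold is off by default; it trades
pseudo-label quality against quantity without a consistent accuracy
benefit.

Degenerate and numerical choices: log arguments are clamped at 1e−12;
argmax ties break to the lowest class index; `hidden_sizes=()` degenerates
to multinomial logistic regression; weight init is He-scaled
(σ = √(2/fan_in)) with zero biases, reproducible from the seed. When the
unlabeled contribution is exactly zero (α(t) = 0, an empty cohort, or an
empty confidence mask), the unlabeled rows are omitted from the batch
entirely, so dropout-mask draws — and hence the whole trajectory — are
bit-identical to supervised training; this reduction is asserted in tests.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| lr_pretrain / epochs_pretrain | 1e−5 / 1500 | supervised phase |
| lr_finetune / epochs_finetune | 1e−3 / 3000 | semi-supervised phase |
| dropout_rate | 0.7 | hidden-activation dropout (training only) |
| l2_coefficient | 1e−4 | weight decay; published work states L2 is used but not its strength |
| T₁, T₂, α_f | 100, 200, 0.05 | unlabeled-weight ramp |
| confidence_threshold | off | strict lower bound on max posterior |
| batch_size | full batch | one update per epoch |

An optional per-class oversampling factor replicates small-class labeled
samples before training — a simple stand-in for generative augmentation of
rare subtypes, which is out of scope.

## Preprocessing

Stage order, applied jointly to all cohorts entering one model:
(1) intersect probe ids across cohorts (the 27K probe set is essentially a
subset of 450K, so intersection harmonizes platforms); (2) remove CpGs
whose missing fraction **strictly** exceeds 20 % ("more than 20 %" read
literally — an exactly-20 % probe survives) in *any* cohort, keeping only
probes that survive everywhere so a single shared feature space remains;
(3) fit the imputer on the pooled labeled cohorts only; (4) apply it to
every cohort. Fitting on labeled data alone prevents fill statistics from
leaking unlabeled/test information. Median imputation is the default (it
performed best in the source study's comparison); mean and KNN are
options. KNN uses nan-aware Euclidean distance over mutually observed
probes and fills with the unweighted mean of the k = 5 nearest training
samples (delegated to scikit-learn's `KNNImputer`, verified against a
brute-force neighbor search in tests). Beta values are used untransformed
— no M-values, no scaling. Batch-effect correction is out of scope; the
synthetic generator's cohort shift exists precisely to show its absence.

## Evaluation metrics

All statistics derive from the C×C confusion matrix: accuracy; macro
(unweighted) precision and recall; per-class F1 combined weighted by
true-class support; the multiclass MCC in Gorodkin's confusion-matrix
form (reducing to the familiar binary MCC at C = 2); and Cohen's kappa
with chance agreement from the marginals. Conventions, fixed for
determinism on degenerate predictors: zero-denominator precision/recall
contribute 0 to the macro mean; MCC with a zero denominator is 0; macro
means average over all C vocabulary classes including classes absent from
the truth, keeping reports comparable across folds. Tests require
agreement with scikit-learn's implementations to 1e−10 on a thousand
random instances.

## Synthetic data

The generator emulates the regime of multi-cohort subtype studies: a small
labeled cohort, a large unlabeled cohort from a different batch, and a
held-out labeled test cohort, with class-conditional beta-value structure.
Background CpGs draw from Beta(2, 2); each subtype owns a disjoint block
of 30 informative CpGs that its members draw from Beta(8, 2)
(hypermethylated, even class indices) or Beta(2, 8) (hypomethylated, odd
indices) — Beta distributions because array beta values are bimodal on
[0, 1]. Missingness is injected completely at random; the unlabeled
cohort receives an additive +0.05 shift, clipped to [0, 1], as a
deliberately crude batch-effect proxy. Defaults: 3 subtypes, 200 CpGs,
40 labeled / 400 unlabeled / 200 test samples.

What the generator does **not** emulate: CpG-island spatial correlation,
probe-level chemistry, realistic platform differences, structured
missingness, or subtype proportions of any real cancer. Passing tests
therefore demonstrate the correctness and internal consistency of the
method, not clinical-grade subtype accuracy on real arrays.

## Benchmark problem sizes

The end-to-end benchmark (`methsubtype.benchmark`) uses hidden sizes
(32, 16) with 300 pre-training and 600 fine-tuning epochs — widths and
budgets proportionate to 200 features and 440 training samples. Both
phases use Adam at 1e−3: the published 1e−5 pre-training rate is matched
to a 1500-epoch budget on ~10⁴–10⁵-feature inputs, and over a 300-step
full-batch budget it cannot move the weights appreciably. Five paired
seeds compare the full pipeline against a pre-training-only ablation on
the same draws; the semi-supervised run must not trail the supervised one
by more than 0.02 mean test accuracy, and pseudo-label accuracy on the
unlabeled cohort is checked at the final epoch.

## Known limitations

- Pure-numpy training is full-batch and CPU-bound; published-scale inputs
  (~10⁴ CpGs, 1000/500 hidden units, 4500 epochs) train in minutes, not
  seconds, and no GPU path exists.
- Pseudo-labeling can reinforce a confidently wrong model; the ramp delays
  but does not eliminate this failure mode, and no calibration of
  posteriors is performed.
- Probe harmonization is id-intersection only; no cross-platform
  remapping, and no batch-effect correction beyond what the labeled data
  teach the model.
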