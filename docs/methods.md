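# Methods

This note documents the models and procedures implemented in `tmesurv`, the
assumptions behind them, and the choices made where the design was genuinely
open. It states no empirical result that the test suite does not itself
compute.

## Problem setting

Gastric tumors can be grouped into four tumor-microenvironment (TME) classes
from two immunohistochemistry axes: the gastric-cancer immune score IS_GC
(a fixed weighted sum of CD3/CD8/CD45RO/CD66b cell densities at the tumor
center and invasive margin) and periostin (POSTN) stromal expression
(stain intensity × extent averaged over five fields). Both axes are
dichotomized at their *training-cohort medians*; the quadrants define
class 1 (immune-high/stroma-low, best prognosis) through class 4
(immune-low/stroma-high, worst). The package implements a multi-task
convolutional model that predicts the TME class and a scalar survival risk
(the deep-learning survival score, DLS) jointly from preoperative CT, plus
the downstream statistics used to evaluate prognostic value, chemotherapy
benefit and anti-PD-1 response.

"Medium value" thresholds are read as the sample median throughout (even n:
mean of the central order statistics); scores exactly at a median count as
"high". IS_GC densities are cells per field, with no extra area
normalization.

## Imaging pipeline

Volumes are indexed `(z, y, x)`, 0-based, with spacing carried on the NIfTI
affine. The deterministic inference path is:

1. **Resampling** to 2.5 × 0.75 × 0.75 mm (z, y, x) by trilinear
   interpolation; masks use nearest-neighbor and are re-binarized at 0.5.
   Output index `j` maps to input coordinate `j·target/source`
   (edge-clamped), so the output grid covers the input extent.
2. **Windowing** to [−150, 150] HU, then an affine map to [0, 1].
3. **Slice selection**: the anchor is the axial slice with maximal in-plane
   mask area; five consecutive slices centered on it are cropped to
   160 × 160 around the anchor-slice mask centroid (rounded to voxels).
   The crop is applied *after* resampling, so its size is in resampled
   voxels. Missing slices at the volume boundary are replaced by the
   nearest edge slice; out-of-plane crop regions are padded with 0 — the
   post-normalization floor, i.e. background-like.

Training-time augmentation (reflections along the anterior/posterior and
left/right axes, random in-plane translation, Gaussian blur, unsharp
sharpening, Laplacian enhancement) is applied per batch with per-transform
probabilities; geometric transforms are drawn once per stack and applied to
all five planes to preserve cross-slice coherence, and outputs are
re-clipped to [0, 1].

## Network

Each slice is embedded by a shared backbone; two fully connected layers
with leaky-ReLU refine the per-slice features `f` (5 × d). A gated
attention module computes

    A = softmax( w3 ( tanh(w1 f + b1) ⊙ sigmoid(w2 f + b2) ) + b3 ),

with the third layer's output dimension equal to the number of tasks
(N = 2) and the softmax taken across the five slices, giving one attention
row per task; `M = A f` is the N × d pooled representation. The per-slice
FC layers are shared across slices and the softmax runs over the slice
axis — the one place where the pooling formula admits more than one
reading; this interpretation keeps attention a distribution over slices
per task. Row 0 of `M` feeds a linear + softmax TME head (4 classes);
row 1 is concatenated with the predicted class probabilities (the
biology→outcome cascade) and passed through two FC layers to the scalar
risk. The cascade is differentiable end-to-end by default; a
`detach_cascade` switch blocks that gradient path for ablations.

Two backbones:

* `resnet18` — the reference: a standard 18-layer residual topology
  (7×7/2 stem, max-pool, four stages of two basic blocks at 64/128/256/512
  channels, global average pooling) followed by a linear projection of the
  512-dim embedding to the canonical per-slice feature size of 256.
  Normalization layers use frozen running statistics (identity by default)
  with learned affine parameters. Weights are randomly initialized
  (He-normal); no pretraining.
* `tiny` — a CPU-scale backbone (d = 64) for tests and synthetic
  experiments: it crops the central 24 × 24 tumor core of each plane
  (the crop is centroid-centered by construction, so the core lies inside
  any admissible phantom lesion), applies a fixed input standardization
  `(x − 0.75)·8`, three stride-2 3×3 conv blocks (8/16/32 channels) with
  leaky-ReLU, global average pooling and a linear map to 64. Pooling over
  the tumor core rather than the full plane reads texture amplitude — the
  class-defining signal of the phantoms — without dilution by background
  or confounding by lesion size.

**Losses.** TME: mean categorical cross-entropy −Σ y log ŷ with the log
clamped at 1e−12. Survival: the negative Cox log partial likelihood

    L = − Σ_{i: E_i=1} [ h_i − log Σ_{j: T_j ≥ T_i} exp(h_j) ],

with risk sets {j : T_j ≥ T_i}; tied event times share risk sets, i.e. the
Breslow convention, which is used consistently here and in every downstream
Cox fit. The log-sum-exp is max-shifted, which also makes the loss exactly
invariant under adding a constant to all scores. The total loss is the
unweighted sum of the two terms (weights configurable for experiments).
Higher risk = higher hazard; any dichotomization cutoff is always the
training-cohort median of the score, never a hard-coded constant.

**Training.** Adam, mini-batches of 16, seeded shuffling; augmentation only
on training batches; batches without events contribute only the
classification term. Divergence (non-finite loss) aborts and restores the
last finite-epoch parameters. Epoch budget and loss-plateau early stopping
are configuration-driven (default max 100 epochs, patience 10 at relative
improvement 1e−4). The learning rate defaults to 1e−3 for the tiny
backbone; the reference GPU-scale recipe (1e−5, as appropriate for a
pretrained-scale model) is available through the same configuration field.
The implementation is pure float64 numpy on a small reverse-mode autodiff
engine written for this package; gradient correctness is enforced by a
finite-difference acceptance test.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume; it
does not emulate CT anatomy, DICOM metadata or scanner noise. Per subject
(all streams spawned from one master seed, so cohorts are reproducible
subject-by-subject):

* **Phantom**: an ellipsoid with random axes (z 4–12, in-plane 12–30
  voxels) near the center of a 40 × 96 × 96 voxel volume at
  2.5 × 0.75 × 0.75 mm. Background is textured (σ = 8 HU around 30 HU);
  tumor voxels are 80 HU plus zero-mean multi-scale texture — the sum of
  two Gaussian-filtered white-noise fields (σ = 1.0 and 2.5 voxels),
  normalized to unit variance and scaled by the class amplitude
  (5, 25, 60, 110 HU for classes 1–4). Heterogeneity strictly increasing
  in class is the imaging signal; the texture correlation lengths are short
  enough that the amplitude is reliably estimable from the tumor core,
  making the classes genuinely separable (with the first-try coarser
  texture, no estimator could separate adjacent classes — an oracle
  standard-deviation feature plateaued near 80% accuracy). Intensities are
  clipped to [−200, 300] HU. Ellipsoid axes under 3 voxels are rejected.
* **IHC**: marker densities are gamma-distributed cells/field, with the
  CD3-IM (or CD66b-IM) density adjusted so the recomputed IS_GC lands a
  clear margin on the intended side of the threshold; POSTN fields are
  composed from achievable intensity×extent products with mean on the
  intended side. With label noise ε, the panel is drawn from a uniformly
  random *other* quadrant with probability ε. Default thresholds: IS_GC 40,
  POSTN 4.
* **Outcomes**: event times follow a Weibull proportional-hazards model
  (shape 1 = exponential by default; the shape is exposed for robustness
  tests) with baseline hazard 0.03/month and per-class log hazard ratios
  (0, 0.8, 1.6, 2.4) plus a weak stage effect (0.2 per level). Clinically,
  prognosis is strongly ordered across the TME classes (reported
  immunotherapy-setting median PFS spans roughly 25 down to 5 months from
  class 1 to 4); per-class hazard ratios for surgical cohorts are not
  published, so these values are the package's choice, made once.
  Censoring is uniform on (0, 60] months, independent of covariates
  (no censoring mechanism is published).
* **Treatment**: chemotherapy is assigned with probability ~0.5, weakly
  confounded by stage (logit slope 0.4) so propensity matching has work to
  do; treated subjects' hazards are multiplied by the class-specific
  hazard ratios 0.258 / 0.691 / 0.831 / 1.669 — the published per-class
  chemotherapy effects.
* **Immunotherapy**: CPS is drawn from a mixture spanning the three
  clinical categories (<1, 1–<10, ≥10 with probabilities 0.3/0.4/0.3);
  objective response follows a logistic model in class and CPS category
  (slope 0.8 per category) whose per-class intercepts are solved
  numerically so the *marginal* per-class response rates equal
  69.0/53.3/18.4/17.2%. Progression-free survival ties to class with a
  response benefit (log HR −1).
* **Clinical covariates** (age, sex, stage, T/N/M, size, CEA, CA19-9,
  location, differentiation, Lauren) are drawn independently of class
  except a weak stage–class correlation (0.3), so multivariable adjustment
  is testable. The joint distribution of class with stage/CEA is not
  published; these knobs make no claim to match the clinical cohorts.

What passing tests therefore show: the pipeline recovers structure it is
told to generate — separable texture classes, proportional-hazards effects,
logistic response models. They do not show that real gastric-cancer CT
carries this signal, and no cohort-level published performance figure is
reproduced here.

## Evaluation statistics

Kaplan–Meier (with Greenwood variance), log-rank, and Harrell's C are
computed with lifelines; Cox models use statsmodels' partial-likelihood
fitter with Breslow ties (lifelines supports only Efron ties), Wald CIs
`exp(β ± 1.96·SE)`; IPCW Brier curves use scikit-survival, integrated by
trapezoid and normalized by the grid span. Implemented in-package because
no installed library provides them:

* **Time-dependent ROC** at a horizon: the KM-based cumulative/dynamic
  estimator (sensitivity and specificity from Kaplan–Meier estimates inside
  the score strata). Cutoffs are walked from high to low so the curve is
  monotone by construction; a running-maximum guard absorbs floating-point
  jitter. Without censoring it reduces exactly to the binary AUC of the
  event-by-horizon indicator.
* **DeLong** paired AUC comparison via placement values (midranks for
  ties).
* **Continuous (category-free) NRI** at a horizon with IPCW weighting of
  events (1/G(T)) and non-events (1/G(t)); bootstrap percentile CI and a
  normal-approximation p from the bootstrap SE. Antisymmetric by
  construction.
* **.632+ prediction-error curves**: bootstrap out-of-bag Brier curves
  combined with the apparent error by the Efron–Tibshirani .632+ weights;
  the no-information error scores every prediction against every outcome
  with IPCW. Resamples whose refit fails are dropped and counted. The
  bootstrap count B is configurable; desk-scale runs use B = 10–50 rather
  than the 1000 a full analysis would use.
* **Calibration**: quantile bins of predicted survival at the horizon vs
  the KM estimate within each bin (Greenwood 95% CI); degenerate bins are
  merged.
* **Variable importance**: per-term Wald χ² (coef²/SE², 1 df) normalized to
  proportions.
* **Integrated model**: Cox on DLS + T/N/M stage, CEA, location,
  differentiation, fitted on the training cohort; risk strata are the 8
  equal-quantile bins of the *training* linear predictor with frozen
  cutpoints (the published 8-group stratification rule is not given;
  quantile binning is the documented stand-in). Unseen categorical levels
  at application raise an error.

No multiple-testing adjustment is applied anywhere (two-tailed p < 0.05
convention).

## Treatment analyses

Chemotherapy benefit: a logistic propensity model on age, sex,
differentiation, CEA, CA19-9, location, T stage, N stage, size and Lauren
type (standardized covariates; separation is flagged as an error), followed
by greedy 1:1 nearest-neighbor matching on the logit propensity without
replacement, treated subjects processed in seeded random order. The caliper
is off by default (none is published); `caliper="auto"` applies 0.2 SD of
the logit scores. Balance is reported as standardized mean differences
pre/post. Within each predicted TME class (optionally × DLS group) the
chemo-vs-none effect is the Breslow Cox HR with a log-rank p; subjects lost
to matching are excluded from stratum estimates. Effect modification is
tested by a Cox model with marker, treatment and their product (Wald p on
the product term).

Immunotherapy: CPS categories use the clinical cutoffs exactly
(high ≥ 10 > intermediate ≥ 1 > low). The composite response model is a
CART (Gini) over one-hot TME class + ordinal CPS category, depth ≤ 3,
minimum leaf 10 — hyperparameters chosen to keep the printed-tree shape
shallow and interpretable; leaf response rates serve as predicted scores.
A single-class outcome yields a trivial root stump rather than an error.
Response reports give ORR per class/category and DeLong AUC comparisons of
CPS-only, class-only and composite scores.

## Pipeline

`tmesurv run-all` executes simulate → preprocess → train → predict →
evaluate → chemo-benefit → immuno-response under one YAML configuration and
a master seed, writing a JSON manifest with the configuration hash and
per-stage output hashes; a stage failure marks the manifest and skips
downstream stages. The cohort manifest stores image paths relative to the
cohort directory, so identical (config, seed) reproduce it byte-for-byte.

## Problem sizes and numerical choices

Desk-scale defaults are deliberate: 200-subject training cohorts,
120–200-subject held-out sets, 60-subject end-to-end smoke runs, bootstrap
B = 10–50, 50-replicate coverage checks, 1000-replicate null calibrations.
Cox convergence uses statsmodels defaults with an explicit finiteness/
magnitude check (|β| < 50 flags monotone likelihood). Cross-entropy clamps
logs at 1e−12; censoring-survival weights are floored at 1e−12; Cox
log-sum-exp is max-shifted. Tie policies: median ties count as "high";
predicted-risk ties count 0.5 in C and AUC statistics; Breslow everywhere
for event-time ties.

## Known limitations

* Phantoms carry a single texture-amplitude signal; real tumors encode TME
  through far subtler morphology. Accuracy figures on phantoms bound
  nothing about clinical CT.
* The reference backbone is validated structurally (topology, feature
  dimension, determinism, gradient correctness), not by training at scale.
* Frozen-statistics normalization departs from train-mode batch norm; at
  GPU scale with pretraining that choice would be revisited.
* The KM-based time-dependent ROC estimator is known not to guarantee
  monotonicity under heavy censoring; the running-maximum guard makes the
  reported curve conservative-monotone.
* PFS for responders is generated with a fixed response benefit; no attempt
  is made to model response-survival dependence realistically.
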