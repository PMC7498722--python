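# Methods

## The pipeline

`neurofuse` implements a subject-level diagnostic pipeline for separating
early mild cognitive impairment (EMCI, label +1) from normal controls (NC,
label −1) using three co-registered scalar volumes per subject: a
T1-weighted structural image (sMRI) and the two standard diffusion-tensor
maps, fractional anisotropy (FA) and mean diffusivity (MD). All three
volumes share one voxel grid (110×110×110 by default).

1. **Normalization and fusion** (`io_fusion`). Each modality volume is
   min–max rescaled to 8 bits using volume-global statistics, 32 axial
   slices with indexes 37–68 (0-based, inclusive) are extracted, and
   same-index slices are stacked into the channels of one RGB composite
   (FA→R, MD→G, sMRI→B). Single-modality experiments replicate one modality
   into all three channels (pseudo-RGB), so the extractor's input contract
   is identical in every arm.
2. **Feature extraction** (`features`). A convolutional backbone with a
   new head — flatten, a 256-unit dense feature layer, a 2-class softmax —
   is fine-tuned on the slice-level dataset (8:2 train/validation split,
   grouped by subject) with RMSProp; the first `frozen_blocks` convolution
   blocks keep their initial weights bit-exactly and the checkpoint with
   minimum validation loss is kept. Each slice yields a 1×256 vector at the
   penultimate layer; a subject's 32 vectors are concatenated in ascending
   slice order into a 1×8192 representation.
3. **Selection and classification** (`select_classify`). Subject features
   are standardized with training-fold statistics (population SD,
   zero-variance columns → 0), a LASSO

       f(θ) = ½‖y − Xθ‖² + λ‖θ‖₁

   selects the nonzero-coefficient columns (cyclic coordinate descent with
   soft-thresholding; numba-compiled inner loop with a pure-numpy
   fallback), and a class-weighted soft-margin SVM
   (sign[wᵀφ(x)+b], penalty ½‖w‖² + cΣξₖ) classifies the selected
   features. λ is chosen per training fold by inner-CV accuracy of the
   LASSO→SVM pipeline over a log-spaced grid ending at λ_max = max_j|Xⱼᵀy|
   (values selecting nothing or more features than training subjects are
   discarded; ties break toward the sparser model). SVM hyperparameters
   come from exhaustive search over a small grid with inner CV. Class
   weights are inverse class frequency, normalized (70:50 → 50/120 for
   EMCI, 70/120 for NC).
4. **Evaluation** (`experiments`). Stratified five-fold cross-validation at
   the subject level: slices of one subject never straddle a fold, the
   extractor is retrained from its initialization per fold on training
   subjects only, and the standardizer, λ and SVM hyperparameters are
   derived from training folds only. Reported metrics are ACC, SEN, SPE and
   AUC in percent (EMCI positive; AUC from decision scores by rank
   statistic), averaged arithmetically over folds. All arms of a comparison
   share folds and seeds.

## Backbone topologies

Two topologies share one engine (same-padded 3×3 convolutions, 2×2 stride-2
max pooling with floor semantics, ReLU):

- `vgg16`: the classic five-block layout (64,64 / 128,128 / 256×3 / 512×3 /
  512×3). On a 110×110 input the first pooling layer emits 64 maps of 55×55
  and the seventh convolution 256 maps of 27×27. ImageNet weights are not
  bundled; `pretrained_weights` loads a local `.npz` export and errors
  clearly on topology mismatch. Default: freeze blocks 1–4, train block 5
  and the head.
- `tiny`: three one-convolution blocks (8, 16, 32 channels), freeze the
  first two blocks by default. This is the workhorse for synthetic
  experiments and tests: it trains in seconds per fold on one CPU.

The head is flatten → dense(256) → dense(2, softmax). Flattening (rather
than global average pooling) preserves the spatial layout of the last
feature maps; the disease signal in both real and synthetic data is
spatially localized, and a location-blind head measurably cripples the
extractor. Inputs are scaled to [0,1]. Loss is softmax cross-entropy.
Training defaults follow the standard recipe (RMSProp, learning rate 1e-4,
batch 32, 50 epochs); synthetic-cohort experiments use 1e-3 and a handful
of epochs because a randomly initialized ~10⁴–10⁵-parameter network, unlike
a warm-started VGG16, needs a larger step and converges quickly at these
problem sizes.

## The phantom generator

`phantom` generates aligned tri-modal cohorts standing in for preprocessed,
co-registered clinical data. Anatomy is an ellipsoidal brain with nested
shells (gray matter, a deep white-matter core, a CSF-like ventricle) plus a
smooth texture field shared by all subjects. Intensity conventions: FA
dimensionless in [0,1] (clipped), MD in 10⁻³ mm²/s (~0.7–0.9 parenchyma,
~2.5 CSF), sMRI arbitrary nonnegative units on an 8-bit-like scale.

Disease effects are additive offsets inside spherical regions. The default
layout places three small regions per modality at the in-plane center of
the white-matter core (uniform template values, away from clipping limits)
at interleaved slice depths inside the 37–68 window, so the signal survives
slice selection. Magnitudes (per region: FA −0.06·s, MD +0.12·s, sMRI
−15·s for effect scale s) are balanced so each modality carries the same
share of signal relative to its own regional-variability floor. Signs
follow neurodegeneration (FA down, MD up, T1 intensity down).

The nuisance model has four parts, all class-independent:

- **Shared anatomical variability**: one smooth random field per subject
  added coherently to all three modalities (scaled to each modality's
  intensity units). Global anatomy differs between people and that
  difference is visible in every modality at once; a multi-channel model
  can contrast channels to cancel it, a single modality cannot.
- **Regional variability**: a random scalar offset per (effect region,
  modality), drawn per subject. This mimics natural inter-subject
  variation in regional intensity and has *exactly the spatial signature of
  the disease effect*, so it bounds single-modality separability at
  d′ = effect/σ_region regardless of classifier quality, while fusing
  modalities pools three independent regions (d′·√3). This is the
  mechanism that makes multi-modality fusion genuinely necessary rather
  than merely decorative.
- **Modality-specific smooth jitter and white voxel noise.**
- **Global intensity-scale jitter** (±5%), removed by min–max
  normalization — it exists so the normalizer has real work to do.

`noise_sd` scales all stochastic components together (0 ⇒ volumes equal
the class template exactly); it multiplies per-modality base noise levels
(sMRI 8.0, FA 0.05, MD 0.08 intensity units) because one number cannot be
simultaneously meaningful across three intensity scales. `shared_noise`
(default 3) and `region_noise` (default 1) set the relative amplitude of
the first two components. The smooth fields' correlation length is 10% of
the smallest volume dimension, comparable to the effect-region radius —
fine-scale jitter would average out of every region mean and constrain
nothing.

Determinism: a cohort is a pure function of its configuration. Subject k's
nuisance stream is keyed by `(subject_noise_seed, k)`, so any subject can
be regenerated independently; the template depends only on
`(shape, anatomy_seed)`.

What the phantom does **not** model: MRI physics, bias fields,
registration error, partial-volume effects, realistic cortical geometry,
site effects. Passing tests on phantoms therefore demonstrates the
*pipeline's* correctness and its ordering behavior under controlled signal
structure — not clinical performance.

## Reference study conditions

Two fixed synthetic conditions drive the headline experiments (also used by
`scripts/acceptance.py`); volumes are in-plane-reduced to 32×32×110 so the
default slice window applies unchanged while a full comparison runs in
minutes on one CPU:

- **Complementary cohort** (60 subjects, 30/30): effect scale 1.75,
  `noise_sd` 0.5, `region_noise` 4.3. Regional variability caps each
  single modality near d′≈1.2 while the fused arm pools nine regions
  across modalities; the region-mean oracle puts singles at ~0.67–0.75 and
  all-modalities at ~0.82, and the learned pipeline lands a few points
  below each. Fine-tuning is brief (2 epochs) — the class effects are
  intensity shifts the extractor picks up quickly.
- **Strong-effect cohort** (40 subjects, 20/20): effect scale 4,
  `noise_sd` 1, `region_noise` 0, nuisance dominated by the shared field.
  Here the untrained extractor is structurally limited (random projections
  cannot cancel the shared field) while eight epochs of fine-tuning learn
  channel-contrast filters, and feature selection prunes the ~8k
  uninformative dimensions; the complete pipeline reaches ceiling (≥95%
  accuracy) and dropping either component costs accuracy.

Ordering assertions average over three pipeline seeds with identical folds
across arms (paired comparisons).

## Numerical choices

- Min–max normalization maps a constant volume to all zeros; 8-bit
  quantization rounds to nearest.
- Slice window ends are 0-based and inclusive; either index base yields 32
  slices, only placement shifts, and the window is configurable.
- Standardization uses the population (divide-by-N) standard deviation.
- Coordinate descent: convergence when the largest coordinate update falls
  below 1e-9 (default), coefficients below 1e-12 snapped to zero; warm
  starts along descending λ paths. Verified against dense grid search
  (d ≤ 3), the soft-threshold closed form, planted-support recovery and an
  independent reference solver.
- SVM decision ties (score exactly 0) map to +1, documented convention.
- AUC uses the rank statistic on decision scores; tied scores earn half
  credit.
- Fold seeds derive from `(seed, fold)` and stay below 2³¹.
- Composites persist as lossless PNG by default (JPEG quality 95 optional);
  lossy storage would break the de-interleaving round-trip.

## Known limitations

- The slicing axis is configurable but no default is claimed anatomically
  correct; the phantom has no real anatomy to privilege one axis.
- ImageNet-pretrained VGG16 weights are not distributed with the package;
  the `vgg16` topology is exercised structurally (shape algebra, freezing,
  random-init forward passes).
- With ~8 training subjects per inner fold the λ grid can skip the narrow
  band of supports between "empty" and "overfit"; denser grids
  (`n_lambdas ≥ 12`) avoid this on very small cohorts.
- Per-fold metrics on small test folds are coarse (one subject = several
  percentage points); dispersion across folds is reported but has no
  external reference point.
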