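# Methods

This note documents the models, numerical conventions and design choices
behind `silistage`, and what its synthetic-data experiments do and do not
demonstrate.

## Problem and data model

The task is binary staging of engineered-stone silicosis: simple silicosis
(SS, label 0) versus progressive massive fibrosis (PMF, label 1, the
positive class). A cohort is a set of patients, each contributing one or
more longitudinal samples; a sample pairs a chest radiograph with 15
measured blood quantities taken at the same visit. Because patients repeat,
the patient — not the sample — is the unit of every train/test split.

## Biomarker panel

From the measured quantities (leukocytes, platelets, the five-part
differential as absolute counts and percentages, ALP, LDH, ACE) six
dimensionless inflammation indices are derived from absolute counts
(standard clinical definitions):

| index | formula |
|---|---|
| NLR | N / L |
| PLR | P / L |
| LMR | L / M |
| SII | N·P / L |
| SIRI | N·M / L |
| AISI | N·M·P / L |

with N, L, M the absolute neutrophil, lymphocyte and monocyte counts and P
the platelet count. An index is missing (NaN, never ±inf or a silent zero)
when any ingredient is missing or a denominator is zero. The resulting
21-marker candidate panel has a fixed, recorded ordering so downstream
concatenation is deterministic. Markers missing in ≥ 20% of cohort samples
(inclusive boundary) are excluded cohort-wide; residual missingness in
retained markers is mean-imputed with *training-fold* means, the imputer
being fold-fitted exactly like the scalers.

## Image preprocessing

The crop is the tightest axis-aligned bounding box (0-based inclusive
coordinates) around all lung pixels of a binary mask, covering both lung
fields jointly with no margin. Resizing is bilinear without antialiasing,
performed in float32 so no intermediate quantization occurs; intensities
are scaled as x/127.5 − 1 exactly, and the grayscale plane is replicated to
three identical channels. Segmentation is a backend slot: an oracle backend
(mask files supplied with the images), an Otsu-plus-two-largest-components
backend adequate for the synthetic fixtures, and room for a learned
segmenter. An anatomically richer segmentation (ribs, mediastinum) can be
plugged into the same slot without changing the pipeline.

## Imaging representation

A frozen backbone maps the preprocessed image to a fixed-length vector; for
a convolutional backbone this is the global average pool of the final
feature map (7×7×1280 → 1280 for the reference architecture). The shipped
default is a seeded random-projection stub (default 64-dim) so the package
runs with no external weights; it is a frozen feature extractor in its own
right, deterministic and test-friendly, but not clinically meaningful.

Within each fold the features are transformed in three train-only phases:
(1) standardization (population SD; constant dimensions get scale 1);
(2) PLS-DA to 15 latent components, implemented as PLS1 against the single
0/1 label — a one-hot two-column response spans the same space, and for a
single response the X-scores are unaffected by whether Y is deflated, so
this matches a classic NIPALS PLS1 with X-only deflation; (3) a second
standardization fitted on the training latent scores. Components are
sign-fixed so each component's largest-magnitude loading is positive,
making comparisons against reference implementations well-posed. The
component count defaults to 15 and is auto-capped at min(n_train − 1, D)
with a warning rather than a hard failure on small folds.

## Fusion

All three architectures use one classifier family at a time — SVM (RBF or
linear, probability estimates via the implementation's internal Platt
calibration), random forest, or gradient-boosted decision trees (LightGBM,
with Bernoulli-style 0.8 subsampling) — each with its hyperparameter grid
searched inside the fold.

* **Early**: image latents (first) concatenated with standardized markers;
  33-dim under defaults; no re-scaling after concatenation.
* **Late**: each branch's mean AUC over 3 patient-grouped internal
  sub-folds of the training set determines the weights
  w_img = AUC_img/(AUC_img+AUC_bio), w_bio symmetric; both-zero AUCs fall
  back to equal weights with a warning rather than an error, keeping
  pathological folds running. The fused probability is thresholded
  inclusively at 0.5 (ties predict PMF).
* **Hybrid**: combines the early-fusion probability with the late-fusion
  probability. Two readings of "weighing early versus late" are defensible,
  so both ship: a simple mean (default) and an AUC-proportional scheme that
  weighs the two branches by their own internal sub-fold AUCs (the late
  branch still using the image/biomarker weights internally). The scheme is
  a config choice and is recorded in every run.

## Cross-validation and metrics

The outer split is a greedy stratified group K-fold (k = 5): patients are
taken largest-first and assigned to the fold where they least increase the
deviation of per-fold *sample-level* class counts from the cohort
proportions — stratification operates on each patient's label multiset, so
mixed-label progressors are handled rather than special-cased. If a class
has fewer patients than folds, or the greedy plan leaves a fold without
both classes, a plain size-balanced group K-fold runs instead and the plan
is flagged unstratified. Hyperparameters are tuned by mean AUC over 3
patient-grouped inner folds (exhaustive grid, first-listed wins ties), then
the winner is refitted on the full outer-training fold.

Per-fold metrics are the PMF-positive confusion quantities — accuracy,
precision, recall, F1 (precision/recall reported as 0 with a warning when
their denominator is empty; F1 is 0 when precision + recall is 0) — plus
the Mann–Whitney rank AUC (ties 0.5). Fold aggregation reports the mean and
a t-interval (k − 1 df, truncated to [0, 1]); the estimator choice is
flagged in reports since several CI conventions exist for CV metrics.

Strategy comparison uses the exact two-sided Wilcoxon signed-rank test on
paired fold AUCs from one shared fold plan (construction fails on
mismatched plans). Zero differences are dropped (classic convention); for
up to 25 nonzero pairs the exact sign-flip distribution of W⁺ is computed
by convolution over (mid)ranks — equivalent to enumerating all 2ⁿ sign
patterns — with a normal approximation beyond that. At k = 5 the smallest
attainable two-sided p is 2/2⁵ = 0.0625, so fold-level significance at
0.05 is unattainable without more folds; this is reported, not hidden.

## Synthetic cohorts

The generator emulates the structure of a real longitudinal staging cohort
with every quantity tunable:

* 94 patients; series lengths truncated-geometric (p = 0.26, range 1–10,
  mean ≈ 3.66), so expected totals ≈ 344 samples;
* initial PMF probability 0.42 plus a 0.15 chance of a mid-series SS→PMF
  conversion (PMF never reverts) puts the expected PMF sample fraction at
  ≈ 0.45; the deterministic `make_reference_fixture` pins the exact
  shape 94/341/187/154 and puts ALP/LDH/ACE at ≥ 20% missingness;
* blood counts are log-normal (σ_log = 0.25) around round clinically
  plausible medians (e.g. lymphocytes 2.0×10⁹/L) — synthetic conventions,
  not estimates of any real cohort. PMF shifts neutrophils (+1σ·effect),
  platelets and monocytes (+0.5σ·effect) and lymphocytes (−1σ·effect), so
  NLR/SII/SIRI/AISI rise with stage as they do clinically; a per-patient
  scalar random effect induces within-patient correlation;
* image features are unit Gaussians plus a class shift of size
  `image_effect` along a planted unit direction and a per-patient offset
  vector — a stand-in for backbone embeddings, not rendered images. Small
  elliptical "radiographs" with masks can additionally be rendered to
  exercise the image pipeline end to end.

Because labels, image features and markers are conditionally independent
given the planted class, orthogonal per-modality signals guarantee an
expected ensemble gain for decision-level fusion — which turns the fusion
claim into a falsifiable property of the implementation rather than of the
data. `complementary_config` fixes a 60-patient, 32-feature configuration
whose effects (image 1.5, biomarker 0.6) were calibrated so each unimodal
branch reaches a cross-validated AUC of roughly 0.75 with this pipeline.

What passing these tests does **not** show: performance on real
radiographs (no texture, no ILO opacity structure is simulated), behavior
under real hematology covariance, or the clinical AUC levels of any real
cohort.

## Problem sizes and run times

The default test and acceptance runs use reduced grids (`QUICK_GRIDS`) and
the sizes above: the null-calibration run uses one full-shape cohort
(~341 samples, all five strategies); the fusion-gain experiment uses 20
seeds of the complementary configuration in the test suite and 5 seeds in
the acceptance script (plus 10 seeds for weight recovery), which keeps a
single-CPU run of either in single-digit minutes while leaving the
Monte-Carlo margins (e.g. ≥ 18/20 wins) interpretable.

## Known limitations

* The stub backbone's features are linear in the input image; experiments
  about *representation* quality require plugging in a real pretrained
  backbone via `BackboneContract`.
* Grid values for the SVM gamma candidates are a package convention
  (`scale`, 0.01, 0.001); they are exposed in config for adjustment.
* CatBoost-style ordered boosting is not included; the gradient-boosted
  family is LightGBM with analogous depth/iteration/regularization grids.
* No decision-curve or calibration analysis; the 0.5 threshold is a fixed
  convention, and AUC is the primary metric throughout.
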