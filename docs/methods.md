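# Methods

`radsurv` implements a multi-lesion CT-radiomics prognostic pipeline for
right-censored time-to-event outcomes (progression-free survival, in
months).  This note documents the models, conventions and design choices;
the README shows how to run the pieces.

## Feature extraction

Volumes are resampled to a common 1 × 1 × 2 mm grid (b-spline interpolation
for intensities, nearest-neighbour for masks) before discretization —
interpolation precedes discretization throughout.  Hounsfield units inside
[−100, 200] HU are discretized into 120 levels of 2.5 HU with half-open bins
`[lower + (k−1)w, lower + kw)` and a closed top bin; in-mask voxels outside
the window are removed from the analysis mask.

Texture families:

* **GLCM** — symmetric co-occurrence matrices at one-voxel displacement over
  the 13 unique 3-D directions (offsets in {−1,0,1}³ minus the origin, with
  antipodal pairs merged).  Features (contrast, dissimilarity, homogeneity,
  energy, entropy in bits, correlation) are computed per direction and
  *averaged* over directions; merging matrices before feature computation is
  the other common convention and was deliberately not used.  For a constant
  region the correlation is undefined and reported as 1.
* **GLRLM** — run-length matrices over the same 13 directions; runs break at
  mask holes and level changes; `RunPercentage = runs / voxels`.
* **GLSZM** — zones are 26-connected equal-level components;
  `ZonePercentage = zones / voxels`;
  `NormalisedZoneSizeNonUniformity = Σ_s n_s² / N_z²`.

Shape features use the voxel-face surface-area convention (stated here
because mesh-based areas are systematically smaller); sphericity is
`π^(1/3) (6V)^(2/3) / A` and the maximum 3-D diameter is computed on the
convex hull of voxel centers.

### Robustness and variance filters

Segmentation-perturbation robustness compares features from the original
mask with a one-voxel, 6-connected erosion (the most conservative reading of
"one voxel") using **ICC(2,1)** — two-way random effects, absolute
agreement, single rater — the standard radiomics test-retest formulation.
A feature is kept iff ICC > 0.85 strictly; zero-variance features have an
undefined ICC and are dropped.  The near-zero-variance filter uses the
common 95/5 convention: drop when the most-common/second-most-common
frequency ratio exceeds 19 *and* distinct values are fewer than 10% of rows.
Center scaling is mean 0 / sample SD 1 (ddof = 1); the fitted parameters are
returned so test folds can be transformed with training-fold statistics.

## Multi-site aggregation and IPITH

Each patient (k ≥ 2 lesions) is summarized by the largest lesion's feature
vector (volume ties broken by smallest lesion identifier), elementwise
min/avg/max over lesions, and intra-patient inter-tumor heterogeneity
(IPITH): the min, mean, max and range of the k(k−1)/2 pairwise distances
between the patient's center-scaled lesion vectors, for six distance types.
Distances are computed on scaled features because unscaled features would
let high-magnitude features dominate the distances; the four summaries are
themselves center scaled across the cohort afterwards.

Conventions on signed, center-scaled data:

* **Minkowski** order defaults to p = 3 (distinct from Euclidean), exposed
  as configuration.
* **Spearman** distance is `1 − ρ` (range 0–2); a constant vector makes ρ
  undefined and the distance is set to 0 with a warning.
* **Jaccard** is ill-defined on signed reals, so the generalized Ruzicka
  form `1 − Σ min(a′,b′)/Σ max(a′,b′)` is used on features min-max rescaled
  to [0, 1] over the cohort; an all-zero denominator gives distance 0.  This
  is a documented substitute preserving the magnitude-profile-similarity
  intent.
* **Canberra** 0/0 terms contribute 0.

## Univariable screening

Every candidate predictor is screened with a univariable Cox model (Efron
tie handling, damped Newton iteration on the partial likelihood; Wald tests
and 95% CIs).  Categorical variables additionally get a log-rank test and
per-level hazard ratios against a reference level; the screen uses the
minimum per-level Wald p.  Variables with p < 0.100 (strict) form the *full*
input; its clinicopathological subset forms the *clinicopathological* input.
The Wald test was chosen over score/likelihood-ratio alternatives as the
convention matching per-level CI reporting.

Correlation pruning visits significantly Spearman-correlated pairs
(p < 0.05) in descending |ρ| with name-based tie-breaks, making the result
order-independent.  Clinicopathological variables are systematically
privileged over radiomics-based ones (the radiomics member is dropped
regardless of p); between two radiomics variables, the one with the higher
univariable p is dropped; clinicopathological–clinicopathological pairs are
both kept.  The survivors form the *uncorrelated* input.

## Survival learners

All five learners share one contract: `fit(X, time, event)`,
`predict_risk(X)` (higher = worse) and `predict_survival(X, times)` with
S(0|x) = 1 and S nonincreasing.  Score-based learners convert risk scores to
curves through a Breslow baseline fitted on training data.

* **Stepwise Cox** — backward elimination from the full model, minimizing
  the partial-likelihood AIC, with the empty model as a legal terminal
  state.  Non-convergent candidate subsets are treated as unavailable.
* **LASSO Cox** — coordinate-descent elastic net at l1_ratio = 1 over a
  short path ending at the requested λ; λ = 0 delegates to the unpenalized
  Newton fit.  Requires a standardized design (the CV engine standardizes
  per training fold).
* **RSF** — 1000 trees, log-rank splitting; tuned over `mtry` and terminal
  node size.  Ensemble survival functions come from the forest itself.
* **GBM** — 1000 sequential trees boosting the Cox partial-likelihood
  gradient; tuned over shrinkage, interaction depth and the minimum
  observations per terminal node.
* **Deepsurv** — a feed-forward network (numpy, manual backprop) emitting a
  scalar log-risk, trained on the negative log Cox partial likelihood with
  risk sets restricted to each mini-batch (Breslow tie handling).  Defaults:
  512 epochs with early stopping (10% validation split, patience 16 —
  protocol fixed here as a design choice), batch 32, batch normalization
  with momentum 0.85, ReLU or SELU activations, adam or momentum-SGD,
  learning rate 0.01 with inverse-time decay `lr₀/(1 + 0.001·epoch)`,
  dropout 0.1.  The regularization constant (default 15) is interpreted as a
  **training-set-size-normalized L2 coefficient** — the penalty is
  `l2_reg/n_train · Σ W²` on weight matrices only — because a raw summed
  penalty of that magnitude at this learning rate collapses the network to a
  constant output; the normalization keeps the printed value meaningful
  across batch and cohort sizes.  With 0 hidden layers, no dropout, zero
  regularization and full-batch training the model is exactly a linear Cox
  model; the test suite asserts it recovers the Newton Cox coefficients
  within 0.05 on a 500-subject simulation.  Batches without events are
  skipped (they carry no partial-likelihood signal).  Zero-event batches,
  per-batch risk sets and the early-stopping protocol are all standard for
  Cox-loss networks; a full-batch mode exists for exactness tests.

Hidden-layer width is per layer (not total).  Default tuning grids cover
λ ∈ 50 log-spaced values, mtry ∈ {1..⌈√p⌉}, nodesize ∈ {5,10,15,20,22,25},
shrinkage ∈ {0.005,0.01,0.05,0.095,0.1}, depth ∈ {1..4}, minimum terminal
observations ∈ {5,8,11,15}, layers ∈ {1,2,3}, nodes ∈ {8..16}, activations
{ReLU, SELU}, optimizers {adam, sgd}.

A fast native Cox fitter (Efron ties, damped Newton with step-halving,
vectorized over untied event times) backs the univariable screen, the
stepwise selection and the λ = 0 path; it agrees with a brute-force
partial-likelihood grid search and with an independent reference
implementation to ~1e−6 in the tests.

## Evaluation

* **Harrell c-index** — comparable pairs are those where the shorter time is
  an event, plus tied-time both-event pairs; tied risks and tied-time
  both-event pairs score 0.5.  This makes `c(risk) + c(−risk) = 1` exactly
  when no risk ties exist.
* **IPCW Brier score** — at horizon t, subjects with an observed event by t
  weigh 1/G(T⁻), subjects still at risk weigh 1/G(t), subjects censored by t
  weigh 0; G is a Kaplan–Meier estimate of the censoring distribution fitted
  on the training partition.  Zero censoring-survival estimates cap the
  weight with a warning; t = 0 contributes 0 by convention.  The integrated
  Brier score is the trapezoidal integral over the 0–24-month grid (3-month
  steps) divided by 24.
* **Repeated stratified CV** — event-stratified 5-fold splits, reseeded per
  repetition from the base seed; per-fold event counts are within one
  subject of proportional allocation; all preprocessing (centering/scaling,
  censoring distribution) is refitted on training folds only.  Folds without
  events trigger a logged re-draw.  Repetition-level fold-averaged c-indices
  are summarized by their mean and 2.5/97.5 percentiles (the interval
  construction is a labelled choice).
* **Distribution comparison** — two-sided paired Wilcoxon signed-rank over
  repetition-level means (the pairing uses identical splits); all-zero
  differences return p = 1.
* **Hyperparameter protocol** — by default each grid point is run through
  the full repeated CV and the best mean c-index is reported.  This mirrors
  reporting one chosen set per model/input but is optimistically biased;
  nesting the scan inside training folds is the unbiased alternative and can
  be built from the same primitives.
* **Permutation importance** — mean c-index loss over 100 seeded shuffles
  per predictor, negatives clipped to 0, scaled to sum to 100%.  If every
  clipped importance is 0 the report is all zeros with a warning.

## Synthetic data

The generator emulates the target study population rather than any real
patient data: ~140 patients, 2–15 lesions each (median ~4, drawn as
2 + Poisson(2.5) clipped to the range), ~83% progression events, median PFS
≈ 6 months.

* **Lesion volumes** (`generate_textured_lesion`) are spherical masks with
  three texture regimes — smooth (Gaussian-filtered field), speckled
  (voxel-wise noise), banded (periodic plates) — controlling in-mask spatial
  autocorrelation.  A lesion flagged as a radiomics target must be ≥ 1 cm³.
* **Feature model** — hierarchical: a patient centroid
  `N(0, patient_effect_sd² I)` in the d = 68-dimensional feature space plus
  independent per-lesion noise with SD
  `heterogeneity_scale × lesion_noise_sd` (defaults 1.0 and 0.5).  The
  hierarchy makes IPITH a well-defined ground-truth quantity: the true
  per-patient Canberra-mean is computed from the raw lesion vectors and
  stored losslessly.
* **Hazard** — Weibull proportional hazards, shape 1.2, scale set so the
  baseline median is 6 months.  The linear predictor combines
  clinicopathological covariate codes, the designated lesion feature
  (feature 0 of the largest lesion) and the true Canberra-mean, the latter
  two z-scored so coefficients read per SD.
* **Censoring** — independent exponential plus an administrative cutoff at
  27 months (a data-collection-horizon analog); the exponential rate is
  calibrated by root-finding so the expected observed-event fraction matches
  the configured target (default 0.829).
* What it does **not** emulate: realistic anatomy or lesion topography,
  correlated feature blocks mirroring real radiomics covariance, informative
  censoring, or measurement error in segmentation.  Passing tests therefore
  demonstrate correctness of the machinery and recoverability of planted
  effects under the stated model, not clinical performance.

## Problem sizes used in the checked runs

The test suite and the acceptance script run scaled-down analogs chosen to
exercise every code path at desk scale: the null calibration and benchmark
use 10 repetitions of 5-fold CV (n = 140 and n = 300), screening recovery
uses 10–20 seeds, and type-I checks use 300–500 simulations.  The engine
itself defaults to the full 100 × 5 design.

## Known limitations

* The feature registry implements the named family subsets, not full parity
  with any external 121-feature list.
* The grid-scan-over-rCV selection protocol is optimistically biased (see
  above); treat reported best-grid c-indices accordingly.
* Deepsurv training is CPU-only and single-threaded by design; very wide
  grids are slow.
* Wavelet/filtered-image features, 2-D extraction, DICOM ingestion,
  competing risks and time-varying covariates are out of scope.
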