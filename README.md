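# radsurv

Multi-lesion CT-radiomics prognostic modelling for right-censored survival
outcomes, built for the metastatic-lung-adenocarcinoma setting where each
patient carries several measurable lesions and the question is whether
single-site and multi-site radiomics carry prognostic information for
progression-free survival (PFS) beyond clinicopathological variables.

The package covers the full chain:

1. **Feature extraction** (`radsurv.preprocess`, `radsurv.texture`,
   `radsurv.features`) — resampling to 1×1×2 mm (b-spline), discretization
   into 120 gray levels of 2.5 HU on [−100, 200] HU, and IBSI-aligned
   histogram, shape, GLCM (13 directions), GLRLM and GLSZM features from
   NIfTI volume/mask pairs.
2. **Filtering** (`radsurv.filters`) — erosion-based robustness via
   ICC(2,1) > 0.85, near-zero-variance removal, center scaling.
3. **Multi-site aggregation** (`radsurv.aggregate`) — per patient: the
   largest lesion's features; elementwise min/avg/max over lesions; and
   intra-patient inter-tumor heterogeneity (IPITH) metrics, i.e. the
   min/mean/max/range of all pairwise lesion–lesion distances in the
   radiomics feature space for six distance types (Euclidean, Spearman,
   Jaccard/Ruzicka, Minkowski, Canberra, Chebyshev).
4. **Univariable screening** (`radsurv.screening`) — Cox Wald tests and
   log-rank, the p < 0.100 candidate filter, and Spearman-correlation
   pruning with clinicopathological variables privileged over radiomics.
5. **Survival learners** (`radsurv.models`, `radsurv.deepsurv`) — stepwise
   Cox (backward AIC), LASSO Cox, random survival forest, gradient-boosted
   Cox, and a Cox partial-likelihood neural network trained on the batched
   loss
   `L = − Σ_{i: δ_i=1} [ s_i − log Σ_{j: t_j ≥ t_i} exp(s_j) ]`,
   all behind one fit/predict-risk/predict-survival contract.
6. **Evaluation** (`radsurv.evaluation`) — Harrell c-index, IPCW
   time-dependent Brier score and integrated Brier score, an
   event-stratified repeated 5-fold cross-validation engine, paired
   Wilcoxon comparison of c-index distributions, and permutation importance
   scaled to 100%.
7. **Synthetic cohorts** (`radsurv.simulate`) — seeded generators for
   textured lesion volumes and multi-lesion cohorts with known ground-truth
   effects (Weibull proportional hazards, ~83% events, median PFS ≈ 6
   months), so the whole pipeline is testable end to end without any data
   download.

See `docs/methods.md` for the modelling conventions and design decisions.

## Worked example

```python
import pandas as pd
from radsurv import aggregate, filters, screening, simulate
from radsurv.evaluation import CVPlan, repeated_stratified_cv, rep_means
from radsurv.models import ModelSpec, one_hot_encode

# a 140-patient cohort whose hazard rises with one lesion feature
# (log HR 0.4 per SD) and falls with inter-lesion heterogeneity
# (true Canberra-mean, log HR -0.3 per SD)
cfg = simulate.CohortSimConfig(n_patients=140, beta_feature=0.4,
                               beta_ipith=-0.3, seed=2)
lesions, patients, outcomes, truth = simulate.generate_cohort(cfg)

feat_cols = [c for c in lesions.columns if c.startswith("f")]
scaled, _ = filters.center_scale(lesions[feat_cols])
lesions_scaled = pd.concat(
    [lesions[["patient_id", "lesion_id", "location", "volume_mm3"]], scaled], axis=1)

pred = aggregate.compute_patient_predictors(lesions_scaled, feat_cols)
pred = pred.loc[outcomes.patient_id]
t, e = outcomes.time_months.to_numpy(), outcomes.event.to_numpy()

for name in ("largest_f000", "canberra_mean"):
    r = screening.fit_univariable_cox(pred[name], t, e, name)
    print(f"{name}: HR {r.hr:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}), p {r.p:.4f}")

X = pred[["largest_f000", "canberra_mean"]]
plan = CVPlan(repetitions=10, folds=5, base_seed=5)
for label in ("stepwise_cox", "gbm", "deepsurv"):
    cv = repeated_stratified_cv(X, t, e, ModelSpec(label), plan)
    print(f"{label}: mean rCV c-index {rep_means(cv).mean():.3f}")
```

prints

```
largest_f000: HR 1.62 (1.29-2.03), p 0.0000
canberra_mean: HR 0.77 (0.64-0.94), p 0.0099
stepwise_cox: mean rCV c-index 0.662
gbm: mean rCV c-index 0.614
deepsurv: mean rCV c-index 0.632
```

The hazard ratios recover the planted directions (the lesion feature is
deleterious, heterogeneity is protective), and all three learners separate
patients well above the 0.5 random baseline in event-stratified repeated
cross-validation.

A command-line interface wraps the same stages:

```bash
radsurv simulate --outdir cohort --seed 1 --n-patients 140
radsurv validate --cohort cohort
radsurv run --outdir run1 --seed 1 --reps 10
radsurv extract --volumes nifti_dir/ --out features.csv
```

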