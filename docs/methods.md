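# Methods

This note documents the statistical procedures the package implements, the
synthetic data they are validated on, and the design choices made where the
design was genuinely open.

## Study setting

The emulated study is a multi-site pregnancy cohort: 81 participants drawn
from 5 birth cohorts, of whom 39 deliver preterm (before 37 completed weeks
of gestation) and 42 at term. Each participant contributes three omics
feature tables measured early in pregnancy — plasma cell-free RNA
transcriptomics, plasma targeted proteomics, and urine metabolomics — plus
clinical covariates (cohort, GA at sampling and at delivery, sample storage
time, maternal age, birthweight). The analysis questions are: can GA at
sampling be estimated from the assays; can PTB be predicted on held-out
participants; and which features carry the PTB signal once cohort structure
is accounted for.

## Synthetic data generator

The generator (`momics.simulate`) is the package's test bed. Per modality
it draws

    X = S L / sqrt(r)  +  cohort shift  +  GA signal  +  PTB signal
        + storage confound (metabolomics only)  +  noise,

with `S` (subjects x r) and `L` (r x features) standard normal. Scaling the
loadings by `1/sqrt(r)` gives the latent part ~unit variance per feature in
every modality, so the latent rank `r` alone controls internal redundancy:
transcriptomics (r = 3) is the widest but most redundant assay,
proteomics (r = 10) and metabolomics (r = 25) less so. This reproduces the
characteristic inversion in which the assay with the most features needs
the fewest principal components to reach 90% variance.

The remaining components:

* **Cohort shift** — N(0, 0.4) per (cohort, feature): a batch effect strong
  enough for a supervised classifier to detect, weak enough that it does
  not dominate unsupervised PCA (cohort silhouette on the first two PCs
  stays below 0.1).
* **GA signal** — 20 features per modality move linearly with standardized
  GA at sampling (coefficient ±1), identically in all cohorts: the
  chronicity-of-pregnancy module. In proteomics one of them is named `PGF`
  (placental growth factor), the target of the urine-surrogate analysis.
* **PTB signal** — 20 features per modality differ between cases and
  controls with effect β = 0.6 (in residual-sd units). A heterogeneity
  fraction h (default 0.5) makes the signal cohort-specific in two ways:
  the effect is the mixture β((1−h)·b + h·s_c) of a shared sign b and a
  per-cohort sign s_c, and the affected columns are additionally rescaled
  per cohort by a lognormal gain exp(h·N(0,1)) — site-specific assay gain.
  Both vanish at h = 0. The gain term is what makes per-cohort
  standardization genuinely necessary: a pooled model fitted on globally
  standardized features faces a different feature scale (hence a different
  effective slope) in every cohort, while per-cohort z-scoring restores a
  common scale. Purely additive sign mixing, by contrast, is largely
  invisible to the distinction — a pooled univariate screen at n = 80
  out-ranks a within-cohort screen at n ≈ 16, and a pooled linear model
  cannot exploit cohort-specific directions in any case.
* **Storage confound** — a random 10% of metabolomics features move with
  standardized storage time (sd 1.0). Storage times are drawn
  independently of delivery GA, so the confound cannot masquerade as
  outcome signal.
* **Truncated normals** for delivery GA (preterm: N(34, 1.5) below 37
  weeks; term: N(39.5, 1) at/above 37) guarantee the exact 39/42 split by
  construction; sampling GA is N(13.6, 3) truncated to (8, delivery − 4)
  weeks; storage is U(100, 1000) days; maternal age N(24.8, 5.3) years;
  birthweight 3300 − 180·max(0, 40 − GA_delivery) + N(0, 150) grams.

Effect sizes are calibrated so the planted behaviours are comfortably
detectable at the default "fast" dimensions (200/100/150 features), and
every planted choice is recorded in a `GroundTruth` object. What the
generator does **not** emulate: count distributions of real cfRNA data,
real panel identities or metabolite chemistry, missingness patterns,
nonlinear effects, or correlated clinical confounding. Tests passing on
this generator therefore demonstrate that the machinery recovers the
structure it models — not that real data contain that structure.

## Quality control

* `modality_complexity` — the number of principal components reaching 90%
  of the variance of the standardized matrix (zero-variance features are
  dropped; the spectrum comes from an exact SVD).
* `pca_embedding` / `lda_embedding` — unsupervised vs cohort-supervised 2-D
  views. LDA shrinks the within-class scatter toward the identity
  (γ = 0.1) because features vastly outnumber subjects.
* `cohort_predictability` / `storage_time_predictability` — 5-fold
  cross-validated random forests (500 trees by default) predicting the
  cohort label (accuracy) or storage time (Spearman of out-of-fold
  predictions). Significance is by label permutation with the add-one
  estimator p = (1 + #{perm ≥ obs}) / (1 + B); the entire cross-validation
  is re-run per permutation. B defaults to 1000; the test suite uses
  30–50 permutations and fewer trees, which bounds the attainable p at
  1/(B+1) and is the problem size those checks are calibrated to.
* `correlation_network_embedding` — t-SNE (fixed seed, perplexity 30
  capped at (F−1)/3, 1000 iterations) on the distance 1 − |Spearman ρ|
  between all features.

## Gestational-age estimation

Outer 10-fold CV over subjects. Per outer training set and modality, a
LassoCV model (inner 5-fold penalty path) maps standardized features to GA
at sampling. The integration layer is non-negative least squares (with
free intercept) on per-modality predictions generated by a second 5-fold
split *inside* the outer training set — the second layer of the two-layer
scheme — and is then applied to the outer test fold. Reported per model:
Spearman ρ of out-of-fold estimates vs truth, raw p (t approximation;
exact enumeration below n = 10), and Bonferroni-adjusted p with factor 4
(three modalities + integrated). Degenerate cases (all-zero lasso under a
null signal) yield constant predictions, which are reported as ρ = 0,
p = 1 rather than an error.

## PTB classification

For each held-out subject (LOOCV), per modality:

1. z-score features with training statistics computed within each cohort
   (a cohort with fewer than 2 training members falls back to global
   statistics);
2. rank features by Wilcoxon rank-sum p computed only on training subjects
   of the held-out subject's cohort (ties: larger |rank-biserial| first,
   then feature id) and keep the top k = 50; if that cohort lacks 2
   training members of either class, selection falls back to the pooled
   training set and the fallback is counted;
3. fit L2-regularized logistic regression, penalty C ∈ {0.01, 0.1, 1}
   chosen by inner stratified 5-fold log-loss.

The integration layer is a logistic model with non-negative modality
weights and per-cohort intercepts, trained on per-modality out-of-fold
probabilities from a stratified 5-fold split of the 80 training subjects
(inner fits reuse the outer-chosen penalty per modality so both layers see
identically calibrated probabilities).

**Class balancing.** Every classifier layer uses class-balanced sample
weights, and the integrator balances classes within each cohort. This is
not cosmetic: under leave-one-out, removing a case tilts the training
prevalence (and, worse, the held-out subject's own cohort prevalence
feeding its intercept) against the held-out label, which drives the
permuted-label null AUROC visibly below 0.5. With per-cohort balancing the
null re-centers at 0.50.

**Performance.** AUROC is the Mann-Whitney statistic
P(case > control) + ½P(tie); the 95% CI is a stratified bootstrap
(2000 resamples, percentile 2.5/97.5) — a bootstrap rather than DeLong CI
because it extends unchanged to the integrated, cross-validated setting.

**Controls and comparators.** `random_label_control` re-runs the entire
pipeline on label permutations that preserve the 39/42 class sizes.
`baseline_comparison` applies the same LOOCV protocol to feature merging
(one model on the concatenated standardized features), plain stacked
generalization (no cohort adjustment anywhere), random-forest and
lasso-logistic baselines on merged features, and the full cohort-adjusted
integration. `covariate_confounding_screen` reports Spearman correlations
of the integrated probability with every clinical covariate (categoricals
expanded one-vs-rest), Benjamini-Hochberg adjusted.

## Feature statistics and enrichment

Per feature, two tests of the PTB contrast: a linear mixed model
`value ~ ptb + (1 | cohort)` fit by REML with a Wald p for the PTB
coefficient (the response is standardized first so the coefficient is a
standardized mean difference; a `standardize=False` mode reports the raw
effect, which is what parameter-recovery simulations check), and the
Wilcoxon rank-sum test (exact enumeration when the smaller class has ≤ 8
subjects and there are no ties, normal approximation with tie correction
otherwise). Wald rather than likelihood-ratio p-values because the screen
runs across tens of thousands of features and the difference is negligible
at these sizes; when the estimated cohort variance collapses the model
reduces to OLS, which is fitted instead and flagged. BH adjustment is
applied within each modality — the assays differ by orders of magnitude in
width, and pooling would let the widest drown the narrowest.

Modules are connected components (≥ 3 members; smaller components stay
unassigned) of the graph joining top features with |Spearman ρ| ≥ 0.6.
Enrichment of a module in a pathway collection is the one-sided Fisher
exact test, p = Σ_{j≥k} C(K,j)·C(N−K, m−j)/C(N,m), over the universe of
features present in the GMT.

## Numerical choices

* The small logistic fits in the LOOCV hot path use an in-package
  Newton/IRLS solver for the standard L2 objective (mean log-loss +
  ‖w‖²/(2Cn), intercept unpenalized); it matches scikit-learn's estimates
  to ~1e-3 and is tested against it. The univariate selection screen uses
  a vectorized rank-sum z-statistic (no continuity correction) — it only
  ranks candidates; reported Wilcoxon p-values always come from the exact
  or tie-corrected test above.
* All randomness flows from a single seed through `numpy.random.
  SeedSequence`; identical seeds give bit-identical datasets and
  predictions.
* Missing cells in input feature matrices are imputed at load time with
  the per-feature median (deterministic and order-independent); the count
  is logged.
* Spearman tests on constant vectors return ρ = 0, p = 1 instead of NaN.
* The integrator falls back to the equal-weight mean of the input
  probabilities if they are all constant, and uses the mean intercept for
  a cohort unseen at fit time.

## Problem sizes used by the test suite

The validation suite runs the full pipeline at the fast-preset dimensions
(81 subjects, 200/100/150 features): 20 permutation pipelines for the
null-control check, 10 seeds for the integration-superiority and
feature-recovery checks (the latter at heterogeneity 0 — with h > 0 some
planted features have near-zero cohort-averaged effect by construction and
no pooled screen can rank them), 50 simulations for mixed-model effect
recovery, and 200 for null-p uniformity. Quality-control significance
checks use 39–49 permutations with 50–60 trees.

## Known limitations

* The generator's effects are linear and homoscedastic; the pipeline's
  behaviour under heavy-tailed or count-valued data is untested.
* Cohort adjustment assumes each cohort contributes both classes; a
  single-class cohort degrades to pooled selection (logged and counted).
* The mixed-model screen fits one feature at a time and ignores
  correlation between features; module detection afterwards is a
  descriptive, threshold-based grouping, not an inferential procedure.
* t-SNE coordinates are seed-reproducible but not comparable across
  datasets or parameter settings.
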