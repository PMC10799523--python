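# Methods

## The model

All three responses — 30-day mortality (0/1, coded 1 = death), plasma PECAM
and plasma sTM — are fitted with the same penalised least-squares model:

Cost(w) = (1/2N) Σᵢ (yᵢ − Σⱼ wⱼ xᵢⱼ)² + λ Σⱼ vⱼ |wⱼ|

where the design columns xⱼ are the Pareto-scaled log metabolite
concentrations (optionally plus clinical covariates), v is a non-negative
per-predictor penalty vector (all ones by default, so the model reduces to
the ordinary LASSO) and λ controls sparsity. Squared error is used for the
binary response too — a linear-probability model. This is deliberate: the
cost being minimised *is* the squared-error form even when y is 0/1, and
the fitted values are used only as ranking scores for ROC analysis, for
which monotone-equivalent logistic scores would give the same AUC. An
L1-penalised logistic variant (`lasso_fit_logistic`, proximal gradient) is
provided for users who want calibrated probabilities, but it is not the
default.

The intercept is unpenalised and handled implicitly: columns are centred
and scaled to unit sample variance (n−1 denominator) and y is centred, so
the intercept equals the raw response mean. Coefficients are reported on
the standardised scale (unit-free, comparable across metabolites);
`coef_raw_scale` maps them back to raw units.

### Solver

Cyclic coordinate descent with exact one-dimensional updates
w_j ← S((1/N) xⱼᵀ r₋ⱼ, λ vⱼ) / (xⱼᵀxⱼ/N), where S is the soft-threshold
operator. Dividing by the column quadratic term makes the update exact for
any column scaling, so the solver does not depend on whether variances use
the n or n−1 convention. Convergence: maximum coefficient change < 1e−7
(default) or 10⁴ sweeps; this tolerance is far below the noise floor of
anything reported downstream. Solutions are certified against the KKT
subgradient conditions (tolerance 1e−6 in tests), and the test suite
cross-checks against scikit-learn's `Lasso` and an independent
bound-constrained split-variable formulation solved with L-BFGS-B.
Features with vⱼ = 0 are never penalised and are excluded from λ_max.
The inner kernels are numba-compiled; the first call in a fresh process
pays a ~2 s compilation cost.

## λ selection

The data sets this pipeline targets are too small for a single
train/validation split, so λ is chosen by a bootstrap-stabilised
cross-validation:

1. Fix a log-spaced grid of `n_grid` values from the full-data λ_max down
   to `grid_ratio`·λ_max (defaults 100 points, ratio 0.001). Using one
   shared grid makes per-bootstrap optima comparable and guarantees the
   median lies on the grid range.
2. For b = 1…B (default 500): resample the N patients with replacement;
   run k-fold CV (default k=5) on the resample, standardising with
   training-fold statistics only; record the λ minimising held-out MSE
   (ties break toward the larger λ, i.e. the sparser model).
3. Report the median of the B optima and refit once on all data at that λ.

A resample whose response is constant has a degenerate CV criterion and is
redrawn (bounded retries, logged). Randomness is consumed through one
`SeedSequence(seed)` whose b-th child drives both the b-th resample and its
fold assignment, so runs are reproducible and individual bootstraps can be
replayed.

Whether the internal folds are redrawn inside each bootstrap (they are
here) or reused, and whether clinical covariates enter the design, are
config choices (`tuning`, `clinical_covariates`) rather than hard-coded
behaviour; the predictor roster actually used is logged in the manifest.

## Preprocessing

Fixed order: feature filter → patient filter → non-positive filter →
imputation → log → Pareto.

* Missingness thresholds are strict: a feature is dropped iff it is missing
  in *more than* 10% of patients (6/52 goes, 5/52 stays); same rule for
  patients over features.
* A feature containing any observed value ≤ 0 is dropped whole — a
  non-positive concentration signals failed quantification, and the log
  transform is undefined there. Cells are never clipped.
* Default imputation is iterative chained random forests with predictive
  mean matching: each incomplete feature is regressed on all others
  (50 trees), missing cells take the observed value of one of 3 donors
  whose out-of-bag predictions are nearest the cell's prediction, and the
  cycle repeats until the mean out-of-bag error stops improving (max 10
  iterations). PMM keeps imputed values inside the observed support, which
  matters before a log transform. KNN (k=5) and per-feature median
  imputers are provided as fast deterministic alternatives. Observed cells
  pass through bit-identically in all methods.
* The log is natural (recorded in the report so results are comparable if
  another base is ever assumed) and Pareto scaling divides the centred log
  by √SD with the n−1 SD convention. Pareto scaling leaves each feature
  with variance equal to the SD of its log values — damping, not
  erasing, variance differences — which is the standard metabolomics
  compromise between no scaling and full autoscaling. Clinical covariates
  are not transformed.

## Cohort statistics

Fisher's exact test is two-sided by the minimum-likelihood rule (sum the
probabilities of all tables with the observed margins whose probability
does not exceed the observed table's). 2×2 tables use the hypergeometric
computation; r×c tables with total ≤ 200 are fully enumerated; larger
tables fall back to seeded Monte-Carlo (Patefield sampling, default 10⁵
draws) with a reported standard error. Mann–Whitney U uses midranks; p is
exact by enumeration for pooled n ≤ 20 without ties, otherwise the normal
approximation with tie and continuity corrections. Summaries are median
(Q1–Q3) with type-7 (R default) quantile interpolation so printed tables
are deterministic. Missing values in a discrete variable are dropped by
default; `include_missing_category=True` makes them a category. No
multiplicity adjustment is applied across the characterisation table rows.

## ROC evaluation

AUC is the rank statistic (concordant pairs plus half the ties)/(n₊·n₋),
identical to the trapezoidal area under the empirical curve and to
U/(n₊·n₋) — an identity the tests verify exactly. Curve thresholds sit at
midpoints between adjacent distinct scores. The default CI is DeLong's
structural-components normal-theory interval clipped to [0,1]; a stratified
bootstrap (B=2000, percentile) is the alternative. Score models are
unpenalised OLS fitted on **all observations** with in-sample fitted values
as scores — matching the small-cohort convention this pipeline mirrors and
documented as optimistic; `cv_linear_scores` provides the held-out
counterpart. Perfectly separated scores give a degenerate DeLong CI with a
warning.

## Over-representation analysis

Selected set = nonzero coefficients of the final fit (default) or top-k by
|coefficient| (`rule: top_k`) — the upstream convention is ambiguous, so
both are exposed. Universe = metabolites that were measured *and* appear in
the pathway collection; pathways with fewer than `min_size` (default 2)
members in the universe are not tested. Raw p = hypergeometric
P(X ≥ overlap); ORA score = −log₁₀(raw p); BH-adjusted p reported
separately (a pathway can have a large score and a modest adjusted p, and
vice versa). Pathway sets enter as GMT files; the bundled
`synthetic_pathways.gmt` is a synthetic collection over the synthetic
cohort's feature names, because real KEGG-derived counts depend on an
external database snapshot the user must supply themselves.

## Synthetic cohorts

`make_cohort` emulates the statistical structure the analysis assumes, not
mass-spectrometry physics:

* log-concentrations ~ multivariate normal, exchangeable correlation
  ρ = 0.2 (a mild, conventional choice — real metabolite covariance is
  block-structured and unknown here), unit log-variance, per-metabolite
  levels drawn once per seed;
* PECAM and sTM = baseline (12 and 16 ng/mL) + sparse linear combination
  of centred log-concentrations + N(0, 0.5²) noise by default;
* mortality events Bernoulli from a logistic link (linear-probability
  optional) calibrated so the expected event count matches, then redrawn
  until exactly `n_deaths` events occur (bounded retries);
* SOFA, septic shock, age, sex and BMI are plausibly distributed
  covariates (SOFA loosely coupled to the mortality risk score);
* missingness is MCAR at a base rate, plus `n_high_missing_features`
  features pushed strictly above the 10% threshold; a MAR option
  preferentially masks low concentrations.

Defaults mirror the target study shape: 52 patients, 63 metabolites,
19 deaths, 13 high-missingness features. The default planted coefficient
vectors share three features across all three responses (two positive, one
negative) so the overlap reporting has known truth.

What the generator does *not* emulate: batch and drift effects, internal-
standard chemistry, censoring-type missingness tied to detection limits
(beyond the MAR flag), non-Gaussian concentration tails, and realistic
clinical-covariate correlation structure. Passing recovery tests therefore
demonstrate correctness of the procedure under the stated generative
assumptions, not performance on real cohorts.

## Numerical and design choices

* Strict ">" in both missingness filters; boundary cases are tested.
* Grid ties in CV resolve to the larger λ; `np.median` (mean of central
  order statistics for even B) defines the median λ.
* Matrices are written with `%.17g` and read with round-trip float parsing
  so file-based and in-memory stage chaining are bit-identical.
* Per-stage seeds derive from the master seed keyed by stage name
  (CRC32 into a `SeedSequence`), so stages rerun in isolation reproduce
  their in-pipeline randomness.
* Test-scale defaults (B=25, 40-point grid) keep the synthetic pipeline
  interactive; `--profile paper` switches to B=500 and a 100-point grid.
  Recovery experiments in the test suite use B=50 with 20 replicates on
  n=100, p=20 cohorts — the smallest sizes at which the procedure's
  behaviour is cleanly separated from noise.

## Known limitations

* In-sample ROC evaluation overstates discrimination; the honest
  cross-validated mode is opt-in.
* The linear-probability mortality model can produce scores outside [0,1];
  harmless for ranking, wrong for calibrated risk.
* Exact r×c Fisher enumeration is exponential in table size; very wide
  tables with total ≤ 200 may be slow (the Monte-Carlo path can be forced
  by lowering `enumeration_limit`).
* Chained-forest imputation inherits random-forest behaviour: with
  uncorrelated features it can do worse than a median fill; it earns its
  keep only when features carry mutual information.
* The bootstrap-median-λ procedure stabilises selection but does not
  remove the optimism of refitting on all data; reported supports are
  candidate panels, not validated biomarkers.
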