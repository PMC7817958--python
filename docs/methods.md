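# Methods

This note documents the statistical model implemented by `resq`, the design
of the synthetic cohort generator, the rationale for the default parameters,
and the main numerical choices.

## 1. Outcome: residual-based resilience

Resilience is operationalized as maintained mental health relative to
experienced stressor load. Let `P` be a participant's internalizing-symptom
total and `E` a stressor-exposure index. The sample's *normative curve* is
the OLS regression of `P` on `E` (linear by default; a quadratic form is
available). The resilience score is the **inverse residual**

```
RES = P̂(E) − P
```

so that participants with *fewer* symptoms than predicted for their exposure
receive *positive* scores. By construction RES has mean zero and is
orthogonal to the exposure regressors in the fitting sample; the test suite
checks both to 1e-8 and checks the fitted coefficients against the
closed-form normal equations to 1e-10.

Three scores are computed: `res_g` against the general-stressor index
`e_g`, `res_s` against the crisis-specific index `e_s`, and `res_c` against
their composite `e_c`.

## 2. Scoring

- **Symptoms.** Twelve items scored 0–3 (Likert), summed to a 0–36 total.
  Missing or out-of-range items raise an error naming the 1-based item.
- **Exposure.** Each endorsed stressor contributes its burden rating
  (1–5); the domain index is the severity-weighted sum over the 11 general
  or 29 crisis-specific items. In strict mode an endorsed item without a
  rating is an error; lenient mode imputes the scale midpoint (3).
- **Composite.** `e_g` and `e_s` are z-normalized (sample SD, ddof = 1) and
  averaged: `e_c = (z_g + z_s) / 2`.

## 3. Cleaning

Five removal rules are applied in a fixed order with first-match
attribution: unparseable age, underage (< 18), missing initial
socio-demographics, pre-final income dropout, missing follow-up
socio-demographics. Remaining records are *valid*; a valid record is
*complete* when all 12 symptom items, all 40 endorsement items, and a
severity for every endorsed item are present (free-text fields are
ignored). The report object carries registered / removed-by-rule / valid /
incomplete / complete counts and enforces their arithmetic consistency.

## 4. Inference

- **Covariate screening.** Each candidate covariate is tested against the
  intercept-only model with a likelihood-ratio test (Gaussian ML, χ² with
  df = number of dummy columns); covariates with p < 0.2 are retained.
- **Directed factor tests.** Each factor enters an OLS model with the
  retained covariates. Reported per factor: the coefficient, classical SE,
  99% Wald CI, two-tailed p, and the adjusted-R² increase over the
  covariate-only model. The study-wide significance threshold is Bonferroni
  corrected: α = 0.01 over 9 factors gives 0.01/9 ≈ 0.0011.
- **Mediation.** Baron–Kenny nested regressions give the total effect `c`,
  direct effect `c′`, and paths `a` (X→M) and `b` (M→Y | X); the identity
  `c = c′ + a·b` holds exactly for nested linear fits on common rows. The
  indirect effect `a·b` gets a first-order delta-method (Sobel) SE,
  `se = sqrt(a²·se_b² + b²·se_a²)`, with an optional second-order term. The
  acceptance suite verifies 99% CI coverage on generated cohorts and ≥95%
  decision agreement with a percentile bootstrap.
- **Penalized ranking.** LASSO under the `(1/2n)·RSS + λ·‖β‖₁`
  parameterization on standardized predictors, a 100-point log-spaced grid
  from `λ_max = max|X'y|/n` down to `10⁻³·λ_max`, 10-fold cross-validation,
  and the **1-SE rule** (largest λ whose mean CV error is within one SE of
  the minimum). Explained variance is reported as the deviance ratio
  `1 − RSS/RSS₀`. Factors are ranked by |coefficient| at the selected λ
  (ties broken by name). *Stability selection* refits over re-randomized
  fold assignments (800 runs in full-scale use; tests use 50) and reports
  per-factor selection frequencies.
- **Subgroups.** For each socio-demographic covariate and factor, one
  interaction model `RES ~ base + covariate + factor + factor:covariate` is
  fitted. Per-level slopes combine the main effect and the level's
  interaction term, with delta-method SEs from the joint covariance; the
  interaction block is tested with a likelihood-ratio test. With no shared
  base covariates this is algebraically equivalent to stratified fits, which
  the tests verify to 1e-8. A sign-consistency audit counts, per factor,
  minority-sign coefficients across levels (zero when all levels agree) and
  confidence intervals crossing zero over all level × factor cells. Small
  gender ("diverse") and diagnosis ("not assessed") categories are excluded
  from subgroup stratification; countries below a size threshold are pooled
  as "Other".

## 5. Synthetic cohort generator

The generator produces cohorts with known ground truth so that every
estimator in the package can be validated against the parameters that made
the data.

1. **Factors.** Nine psycho-social factors are drawn from a multivariate
   normal with a plausible correlation structure (Cholesky factorization;
   non-positive-definite inputs are rejected). Two structural equations
   overwrite the draws to create mediation paths:
   `PAS = a₁·PSS + √(1−a₁²)·disturbance` and
   `REC = a₂·PAS + √(1−a₂²)·disturbance`, keeping unit variances.
2. **Exposure.** Endorsements use a Gaussian-copula construction with a
   shared exposure propensity (weight 0.5) so the two domain sums correlate
   strongly (≈ 0.62–0.64 at the defaults), matching the regime of real
   lockdown surveys. Severities are drawn from a 1–5 distribution.
3. **Symptoms.** A continuous symptom level
   `P = 15.5 + 4·E_true − Σ w_k·F_k + covariate shifts + N(0, 4²)`
   is discretized onto the 12 items by largest-remainder apportionment, so
   the item total equals the rounded target exactly.
4. **Missingness and defects.** A configurable fraction of records is made
   incomplete; invalid records (bad age strings, underage, dropout
   patterns) can be injected with known labels for round-trip testing.

Reproducibility uses named substreams
(`np.random.default_rng([seed, label])`): the same seed always yields a
bit-identical cohort, and each stage's draws are independent of the others.

### Default parameters

- `n_participants=2000`, `seed=0`.
- **Factor weights** (symptom points per factor SD): pas 0.75, pss 0.65,
  css 0.36, opt 0.84, gse 0.70, rec 0.98, neu −0.87, bcs 0.22, pac 0.90.
  These are scaled so the factor block explains a realistic share of the
  resilience variance (deviance ratio ≈ 0.3–0.4 and standardized effects of
  roughly 0.25–0.5 SD), rather than the much weaker regime produced by
  interpreting standardized coefficients as raw symptom points.
- `symptom_intercept=15.5`, `exposure_slope=4.0`, `noise_sd=4.0`: yields
  symptom totals near 16 ± 6 on the 0–36 scale.
- `shared_propensity=0.5`: induces the ≈ 0.62 general/specific exposure
  correlation.
- `missingness=0.155`: the incomplete fraction typical of long online
  surveys.
- `covariate_effects={"diagnosis": {"yes": +2.8}}`: a current or past
  psychiatric diagnosis shifts symptoms upward.
- `mediation_paths={"a1": 0.5, "a2": 0.5}`.
- Per-subgroup `weight_modifiers` allow a factor's weight to differ in a
  covariate stratum (used to validate the moderation machinery).

## 6. Numerical choices

- OLS fits use statsmodels; design matrices are built explicitly with
  dummy coding against the most frequent level as reference, and a QR rank
  check raises a dedicated `CollinearityError` before fitting.
- The LASSO path is computed by scikit-learn's coordinate descent
  (`lasso_path`); `λ = 0` falls back to least squares.
- All randomized procedures take explicit seeds / `random_state` and are
  deterministic given them; the pipeline report embeds a SHA-256
  configuration hash, the seed, and the package version, and reruns are
  byte-identical.
- Test problem sizes are chosen for calibration power within a desktop
  budget: e.g. 100 seeds × n = 5,000 for weight recovery, 100 replicates
  for mediation CI coverage, 500 null replicates for the interaction
  likelihood-ratio type-I error, 50 stability runs, and 20 seeds ×
  n = 10,000 for the subgroup sign audit.

## 7. Limitations

- The generator's structural equations are linear and Gaussian; it does not
  model floor effects in symptom items, informative missingness, or
  measurement error in the factor scales.
- The residual-based resilience score is relative to the study sample: it
  re-centers in every cohort, so scores are not comparable across cohorts
  with different normative curves.
- The Sobel interval is asymptotic; for small samples a bootstrap interval
  is preferable (the acceptance suite quantifies their agreement at
  n = 300).
- Cross-sectional data cannot establish the causal direction of the
  factor–resilience associations; the directed tests encode hypotheses, not
  causal identification.
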