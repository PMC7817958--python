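# resq — residual-based resilience analysis for stressor-exposure surveys

`resq` implements an outcome-based, cross-sectional resilience analysis for
survey cohorts. Rather than treating resilience as a trait questionnaire
score, it operationalizes resilience as *maintained mental health relative to
experienced stressor load*: the inverse residual of a participant's observed
internalizing-symptom total against the sample's own normative
exposure-to-symptom regression. Participants below the normative curve
(fewer symptoms than expected for their exposure) receive positive scores.

The package bundles everything needed to run and validate such an analysis
end to end:

- a **synthetic cohort generator** with known ground truth (factor weights,
  mediation paths, exposure effects), so every estimator can be checked
  against the parameters that produced the data;
- **cleaning** with ordered removal rules and a completeness classification;
- **scoring**: 12-item symptom totals (Likert 0–3, range 0–36),
  severity-weighted stressor-exposure sums for a general and a
  crisis-specific domain, and their z-score composite;
- **resilience scores** as inverse residuals against linear (or quadratic)
  normative curves for each exposure index;
- **covariate screening** (likelihood-ratio tests at p < 0.2) and directed
  factor regressions with 99% confidence intervals and a Bonferroni-corrected
  significance threshold;
- **mediation** via the Baron–Kenny nested-regression approach with an
  asymptotic-normal (delta-method) confidence interval for the indirect
  effect;
- **penalized factor ranking**: cross-validated LASSO with the 1-SE rule,
  deviance ratios, and stability selection over repeated re-randomized runs;
- **subgroup analysis**: factor-by-covariate interaction models with
  per-level slopes, a likelihood-ratio moderation test, per-level penalized
  rankings, and a sign-consistency audit across the full subgroup grid;
- a **CLI** (`resq`) with one subcommand per stage plus a single-command
  pipeline that writes CSV intermediates and a reproducible JSON report.

## Worked example

The snippet below simulates a 2,000-person cohort, cleans and scores it,
fits the normative curve, and runs the main analyses. All numbers shown are
the actual output for this seed.

```python
import numpy as np
import resq

cfg = resq.default_config(n_participants=2000, seed=7)
cohort, truth = resq.generate_cohort(cfg)

participants, report = resq.clean(cohort)
complete = participants[participants["complete"]].reset_index(drop=True)
res = resq.compute_all(resq.score_cohort(complete))

print(len(cohort), report.n_complete)
# 2000 1672

print("P mean %.1f sd %.1f" % (res["P"].mean(), res["P"].std(ddof=1)))
# P mean 16.2 sd 6.4

print("corr(e_g, e_s) = %.2f" % np.corrcoef(res["e_g"], res["e_s"])[0, 1])
# corr(e_g, e_s) = 0.62
```

Covariate screening retains only covariates that improve the null model at
p < 0.2; the directed factor test then adjusts for them:

```python
screening = resq.screen_covariates(
    res, "res_c",
    ["gender", "age_years", "income_band", "education_years",
     "diagnosis", "employment"],
)
retained = [c for c in screening.index if screening.loc[c, "retained"]]
print(retained)
# ['diagnosis']

fit = resq.test_factor(res, "res_c", "pas", retained)
print("beta=%.3f  99%% CI (%.3f, %.3f)  p=%.1e" %
      (fit.beta, fit.ci_low, fit.ci_high, fit.p))
# beta=2.722  99% CI (2.440, 3.004)  p=2.3e-116
```

Mediation (perceived social support acting through positive appraisal
style) and the penalized factor ranking:

```python
med = resq.baron_kenny(res, "pss", "pas", "res_c", covariates=retained)
print("a=%.3f b=%.3f c=%.3f c'=%.3f indirect=%.3f CI (%.3f, %.3f)" %
      (med.a, med.b, med.c, med.c_prime, med.indirect, med.ci_low, med.ci_high))
# a=0.495 b=2.650 c=1.456 c'=0.145 indirect=1.311 CI (1.094, 1.528)

ranker = resq.LassoFactorRanker(random_state=7).fit(
    res[list(resq.FACTORS)], res["res_c"].to_numpy()
)
print(ranker.rank())
# {'pas': 1, 'rec': 2, 'opt': 3, 'gse': 4, 'pac': 5,
#  'neu': 6, 'pss': 7, 'css': 8, 'bcs': 9}
print("deviance ratio %.2f" % ranker.deviance_ratio_)
# deviance ratio 0.35
```

Stability selection over 50 re-randomized cross-validation runs keeps every
informative factor in all runs and drops the weakest one entirely:

```python
print(ranker.stability(runs=50))
# {'pas': 1.0, 'pss': 1.0, 'css': 1.0, 'opt': 1.0, 'gse': 1.0,
#  'rec': 1.0, 'neu': 1.0, 'bcs': 0.0, 'pac': 1.0}
```

The same pipeline is available from the command line:

```bash
resq run --seed 7 --outdir out/     # writes out/report.json and CSVs
resq simulate --seed 7 --n 2000 --out cohort.csv
resq clean --in cohort.csv --out participants.csv
```

## Testing and reproduction

```bash
python -m pytest -q tests/
```

The suite covers closed-form oracles (normal equations, soft-thresholding,
Sobel arithmetic), statistical calibration (CI coverage, type-I error
rates), and whole-pipeline parameter recovery against the generator's
ground truth. `tests/test_acceptance.py` holds one test per release
criterion.

The headline acceptance metric can be regenerated with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes `{"t6": {"value": 36.0, "n": 12}}` — the maximum attainable
12-item symptom total under 0–3 per-item scoring. All analyses are
deterministic given a seed; `resq run` embeds a configuration hash, the
seed, and the package version in its report so reruns can be verified byte
for byte.

See `docs/methods.md` for the statistical methods, generator design, and
default-parameter rationale.
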