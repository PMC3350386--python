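# psivar

Empirical-properties toolkit for hospital Patient Safety Indicators (PSI)
computed from discharge abstracts. Given discharge-level records (or a
synthetic generator with known ground truth), the package answers three
questions about an indicator:

1. **Is between-hospital variation systematic rather than random?**
   Percentile ratios of hospital rates (RV95-5, RV75-25) and the variance of
   hospital log relative risks under a Poisson–lognormal hierarchical model
   (the "EB" statistic), with nonparametric cluster-bootstrap percentile
   intervals (default 2,000 resamples).
2. **How much outcome variation sits at the hospital level?**
   Two-level random-intercept logistic models (model sequence: random
   intercept only → + age/sex → + screened comorbidities), estimated by a
   Laplace approximation (adaptive Gauss–Hermite as a cross-check), with the
   latent-variable intraclass correlation `rho = σ²/(σ²+π²/3)` and the
   Median Odds Ratio `MOR = exp(√(2σ²)·Φ⁻¹(0.75))`.
3. **Which hospitals sit above/below the expected rate?**
   Shrunken residuals (conditional posterior modes of the hospital effects)
   with comparative standard errors, outlier flagging, caterpillar plot
   data, and comparisons across model variants (largest-hospitals subset;
   coding-intensity recalibration).

Patient-level risk adjustment uses main-effects logistic regression
(age, sex, binary comorbidities screened at adjusted OR ≥ 2), expected
counts from summed fitted probabilities, and indirect standardisation
(O/E × pooled rate, per 1,000). Hospitals with fewer than 30 eligible cases
are excluded by default.

## Layout

| module | contents |
| --- | --- |
| `psivar.synthetic` | discharge-level and count-level generators with recorded ground truth |
| `psivar.cohort` | comorbidity mapping, eligibility/event rules, hospital filters, subsets |
| `psivar.riskadjust` | IRLS logistic fit, covariate screening, c-statistic, O/E summaries |
| `psivar.variation` | RV ratios, Poisson–lognormal variance, cluster bootstrap |
| `psivar.glmm` | random-intercept logistic (Laplace/AGQ), rho, MOR, model sequence |
| `psivar.profiling` | shrunken residuals, flagging, caterpillar data, variant comparison |
| `psivar.runner` | `RunConfig`, `run_analysis`, and the `psivar` command-line interface |

Comorbidity flags in the synthetic generator are drawn independently; real
comorbidities co-occur, but no joint law is assumed (or needed by the
estimators under test).

## CLI

Runs are driven by one YAML config (see `RunConfig` for every field):

```yaml
seed: 7
output_dir: out
min_cases: 30
bootstrap_reps: 2000
alpha: 0.05
synthetic:
  n_hospitals: 150
  sigma2_hospital: 0.3
  hospital_size_mean: 800
  beta: {intercept: -4.5, age: 0.02, sex: 0.1, paralysis: 1.62}
  comorbidity_prevalences: {paralysis: 0.03}
```

```bash
psivar simulate --config config.yaml          # write synthetic tables
psivar run-all  --config config.yaml          # full pipeline
psivar run-all  --config config.yaml --seed 11 --out elsewhere/
```

Outputs are delimited-text tables (variation report, model-sequence table,
hospital summaries, caterpillar data, exclusion log) plus a JSON manifest
with a config hash and per-file checksums; reruns with the same config are
bit-identical. Instead of `synthetic:`, a `discharges_path:` (CSV with
`hospital_id, age, sex, <comorbidity flags>, n_secondary_dx,
eligible_<psi>, event_<psi>`) analyses real data.

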