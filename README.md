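# healthineq

Survey-weighted measurement and decomposition of socioeconomic inequality in
binary health outcomes — concentration curves, the standard and
Erreygers-normalized concentration indices with design-based uncertainty, and
regression-based decomposition of the inequality into covariate
contributions. The package targets analysts of pooled Demographic and Health
Survey (DHS)-style data who rank women by an ordinal equity stratifier such
as an empowerment index and ask how unequally maternal health services
(antenatal and postnatal care) are distributed across that ranking, and why.

## The statistics

With `h` a binary outcome, `μ` its weighted prevalence, and `r` the weighted
fractional rank of each woman on the stratifier (tied ordinal categories
share their category-midpoint rank, so the weighted mean rank is exactly ½):

- **Concentration index**: `CI = (2/μ) · cov_w(h, r)` — twice the area
  between the concentration curve and the line of equality; positive when
  the outcome is concentrated among the higher-ranked (advantaged) groups.
- **Erreygers normalized index**: `ECI = 4μ·CI / (y_max − y_min) = 8·cov_w(h, r)`
  for a binary outcome (range 1). It measures absolute inequality and
  satisfies the mirror property `ECI(1−h) = −ECI(h)`, so attainment and
  shortfall inequality agree up to sign.
- **Uncertainty**: cluster-robust variance of the convenient-regression
  slope of `h` on `r` (Taylor-linearization practice), or a stratified
  cluster bootstrap.
- **Decomposition**: from a survey-weighted binomial-logit fit, each dummy
  regressor `k` gets an elasticity `ME_k · x̄_k / μ` (derivative-form average
  marginal effect `ME_k = β_k · mean_w[p(1−p)]`), its own concentration
  index `CI_k` against the same rank, and a percent contribution
  `100 · elasticity_k · CI_k / CI`; contributions plus an explicit residual
  total 100%. Positive contributions widen, negative narrow, the measured
  inequality.

Supporting machinery: outcome construction from service components (early
skilled antenatal care, 4+ visits, quality antenatal care = blood pressure +
blood test + urine test, postnatal care within two days),
least-advantaged-category recoding of "don't know" responses, pooled-survey
weight rescaling so each round counts equally with collision-free
stratum/cluster IDs, SWPER-style empowerment scoring from 14 items
(loadings are configuration — see `healthineq/data/swper_synthetic_weights.yaml`,
a synthetic template), and a DHS-like synthetic survey generator with
enumerated ground truth so the whole pipeline is testable without
restricted microdata.

## Worked example

```python
from healthineq import (GeneratorConfig, generate_pooled_survey, pool_and_rescale,
    fractional_rank, erreygers_result, fit_outcome_model, build_design_matrix,
    decompose)

cfg = GeneratorConfig(n_surveys=2, survey_years=(2011, 2016),
                      strata_per_survey=10, clusters_per_stratum=8,
                      women_per_cluster=25, seed=1)
df, truth = generate_pooled_survey(cfg)
df = pool_and_rescale(df)

domain, outcome = "attitude_to_violence", "quality_anc"
sub = df[df[domain].notna()]
rk = fractional_rank(sub[domain], sub["rescaled_weight"],
                     order=["low", "medium", "high"])
res = erreygers_result(sub[outcome].to_numpy(float), rk,
                       cluster=sub["unique_cluster"].to_numpy())
print(f"prevalence {res.prevalence:.3f}  ECI {res.eci:.3f} "
      f"(95% CI {res.ci95[0]:.3f}, {res.ci95[1]:.3f})")

covs = {"residence": "rural", "wealth": "poorest", "education": "none",
        "media_exposure": "none", "occupation": "none", domain: "low"}
fit = fit_outcome_model(sub, outcome, covs, weights="rescaled_weight")
X, _ = build_design_matrix(sub, covs)
dt = decompose(fit, rk, res, dummies=X, outcome=outcome, domain=domain)
print(dt.to_frame(decimals=3).to_string(index=False))
```

prints

```
prevalence 0.508  ECI 0.189 (95% CI 0.157, 0.220)
           covariate     level  elasticity     CI      %
           residence     urban       0.078  0.084  7.031
              wealth    middle       0.012 -0.011 -0.150
              wealth    poorer       0.006 -0.106 -0.664
              wealth    richer       0.043  0.050  2.341
              wealth   richest       0.097  0.191 19.858
           education    higher       0.015  0.252  4.027
           education   primary       0.012  0.109  1.427
           education secondary       0.026  0.213  5.982
      media_exposure       one       0.032  0.116  3.987
      media_exposure     three       0.002  0.440  0.903
      media_exposure       two       0.006  0.217  1.326
          occupation   working      -0.007  0.034 -0.250
attitude_to_violence      high       0.046  0.800 40.011
attitude_to_violence    medium       0.031  0.400 13.323
            residual                   NaN    NaN  0.848
```

Quality antenatal care is used by half the simulated women (prevalence
0.508) but is concentrated among the more empowered: ECI 0.189, confidence
interval well above zero, and close to the generator's enumerated population
truth of 0.182. The decomposition attributes most of the measured inequality
to the empowerment gradient itself (40.0% + 13.3%) and to the wealth and
education gradients that correlate with it; the residual left by the
linear approximation is under 1%.

The same analysis is available from the shell:

```bash
healthineq generate --seed 1 --out pooled
healthineq prepare pooled.csv prepared.csv
healthineq analyze prepared.csv --outcome quality_anc --domain attitude_to_violence
healthineq run -c run.yaml     # full outcome x domain grid from a config file
```

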