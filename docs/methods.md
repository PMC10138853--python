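# Methods

## Ranking and the concentration index

Women are ordered by an ordinal equity stratifier (three-level empowerment
domains by default). Because the stratifier has few levels, ties dominate:
every member of category `c` with weighted share `w_c` and cumulative share
`W_c` below it receives the category-midpoint fractional rank
`r = W_c + w_c/2`. This makes the weighted mean rank exactly ½, leaves ranks
invariant to rescaling all weights, and is the standard construction for
grouped rankers; within-category order is undefined and no attempt is made
to break ties.

The standard concentration index is `CI = (2/μ)·cov_w(h, r)`; for binary
outcomes the package reports the Erreygers normalization
`ECI = 4μ·CI = 8·cov_w(h, r)`, which is bounded in [−1, 1], equals
`4p(1−p)` when the outcome is held entirely by a top category of share `p`,
and obeys the mirror property. Numerically the ECI is computed in the
symmetrized form `4·[cov_w(h, r) − cov_w(1−h, r)]`: the two covariances are
equal and opposite in exact arithmetic, and averaging them makes
`ECI(1−h) = −ECI(h)` hold bit-for-bit rather than to one ulp. Non-binary
outcomes are rejected by the Erreygers routines and served by the standard
index.

Concentration curves are reported as vertices at cumulative category
boundaries (the curve is piecewise linear because tied women share a rank);
twice the signed area between the diagonal and the curve reproduces the
standard CI, which the tests verify by trapezoidal integration.

## Uncertainty

The default standard error comes from the "convenient regression": the
weighted slope of `h` on `r` equals `cov_w(h, r)/var_w(r)`, so
`8·var_w(r)·slope` is algebraically the ECI, and the cluster-robust variance
of the slope (statsmodels WLS, CR1) scaled by `8·var_w(r)` gives its SE.
This matches Taylor-linearized survey practice where clusters are the
primary sampling units; strata enter through the alternative estimator, a
stratified cluster bootstrap (clusters resampled with replacement within
strata, ranks recomputed per resample, percentile intervals; default 1000
replicates, seeded). The two can differ in the third decimal; both record
their method in the result. Intervals are fixed at 95%. A constant outcome
yields a point mass at zero (SE 0, degenerate interval). Replicates whose
resample collapses to a single stratifier category are skipped; strata with
a single cluster raise an error under the bootstrap, and the pipeline
optionally collapses such strata into their nearest neighbour (by sorted
label) with a logged warning.

## Decomposition

A survey-weighted GLM with binomial family and logit link is fit per
outcome (statsmodels, `var_weights`; point estimates are invariant to weight
rescaling). Covariates are dummy-coded against declared reference
categories; collinear columns are dropped by pivoted QR with a warning and
recorded on the fit. Non-convergent fits restart from a small-ridge
(`alpha = 1e-4`) solution before failing — sparse many-level covariates
(e.g. a 20-category ethnicity variable) are the motivating case.

Average marginal effects use the derivative form
`ME_k = β_k · mean_w[p(1−p)]`, not the discrete change. The decomposition is
a linearization `CI ≈ Σ_k (ME_k x̄_k/μ)·CI_k`, and only derivative-form
elasticities keep that identity additive; discrete-change effects (the
default in some software) break it. Percent contributions divide by the
outcome's standard CI, so they are identical whether the standard or the
Erreygers index is decomposed (the `4μ` cancels); the residual
`100 − Σ contributions` — the generalized error-concentration term — is
reported explicitly because additivity is the key testable identity. When
the outcome CI is zero, percent shares are undefined and the package raises
with advice to report absolute contributions. The stratifier's own dummies
enter the covariate list like any other block; with a moderate-effect
outcome driven only by the stratifier the block recovers nearly all of the
inequality, but the residual is linearization error, systematic rather than
stochastic, so exact 100% attribution is not expected and not asserted.

## Empowerment scoring

Domain scores are linear: `Σ_j loading_j (item_j − center_j)/scale_j`, with
two increasing cutpoints mapping scores to low/medium/high; a score equal to
a cutpoint promotes (left-closed upper side — the convention is arbitrary
but documented and tested). Principal-component loadings are consumed as
configuration, never re-estimated: deriving them requires multi-country
microdata out of scope here. The bundled
`data/swper_synthetic_weights.yaml` is a synthetic, clearly-labelled
template carrying the 14 standard item names; published SWPER Global values
can be pasted in verbatim. The decision-making domain may be absent from a
survey round; its rows score NA and drop out of that domain's analyses only.

## Synthetic data generator

The generator emulates a pooled DHS-like series: `n_surveys` rounds, each
with region×urban/rural strata (alternating urban/rural), equal-sized
clusters as PSUs, and lognormal cluster-level weight factors
(`weight_dispersion` = 0.3 on the log scale) normalized to mean 1 per survey
— weights are selection noise independent of covariates. Dependence between
the stratifier and the socioeconomic covariates comes from one latent
"socioeconomic position" factor per woman (urban shift 0.8, cluster random
intercept sd 0.3, unit individual noise); each ordinal variable thresholds
its own Gaussian draw correlated with the standardized factor through a
per-variable loading (Gaussian copula). Outcomes are Bernoulli draws from a
logit model in the realized covariate dummies plus a linear survey-round
drift (0.25 per round). Defaults — category shares for wealth, education,
media exposure, occupation, religion and the three empowerment domains, and
log-odds between 0.15 and 1.1 — are set to the magnitudes seen in pooled
low-income-country maternal-health surveys, giving outcome prevalences of
roughly 0.2–0.5 and population ECIs of roughly 0.08–0.24. The
decision-making domain can be omitted from the earliest round, mirroring
series where it was not collected. One seed stream is split deterministically
per survey, so any single survey regenerates byte-identically.

Ground truth is enumerated over a seeded iid superpopulation (default 10⁶)
drawn from the same covariate process at the design's urban share with equal
weights: since ranks depend only on the stratifier category and outcomes are
conditionally independent given covariates, the true ECI is
`8·cov(p_i, r_i)` over conditional outcome probabilities — no outcome
sampling noise enters the truth, only the covariate draw (Monte-Carlo error
≈ 1e-3 at 10⁶). Recovery tests use 200 replicates of a 2-survey × 20-strata
× 10-cluster × 25-women design (10 000 women per replicate), a size chosen
to give ~400 clusters so cluster-robust intervals are trustworthy while the
full simulation stays fast.

What the generator does **not** emulate: real DHS geography or census
frames, household rosters, probability-proportional-to-size cluster
selection, informative (covariate-dependent) weights, nonresponse, or
cluster-level effects entering the outcome directly (clustering of outcomes
arises only through clustered covariates — enough to make naive SEs wrong
and cluster-robust ones necessary, but milder than real-world intracluster
correlation). Passing tests therefore demonstrate the estimators' internal
correctness and their statistical behavior under a faithful two-stage
weighted design, not agreement with any real country's survey estimates.

## Degenerate inputs and numerical choices

Single-category stratifiers raise a dedicated error everywhere (ranking is
undefined); zero prevalence raises (the index divides by μ); truth
enumeration records NaN for a degenerate domain rather than failing
generation. "Don't know" recoding never changes row counts. Pooled
rescaling uses target total 1 per survey (any common constant satisfies
"each survey counts equally"). Oracle agreement between the covariance,
slope and curve-area routes is asserted at 1e-6; the closed forms at 1e-9
or tighter; the additivity identity at 1e-6.

## Known limitations

- Percent contributions are ratios of noisy quantities; near-zero outcome
  CIs make them unstable (the null tests compare them to their permutation
  distribution rather than to zero).
- No standard errors on individual contributions, no dominance tests
  between curves, no Wagstaff or ν-parameter index families, and no
  two-group (Oaxaca-type) or over-time decompositions.
- The linearized and bootstrap intervals may disagree in the third decimal;
  neither is privileged.
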