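# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the package's tests demonstrate.

## 1. The data-generating process (`mistreat.dgp`)

Welfare, adoption and the self report follow

* `W* = δ T* + μ` — linear outcome equation with true effect δ
  (default 0.3, i.e. a 30% effect on a log-scale outcome);
* `T* = 1[φ'z + ω > 0]` — threshold-crossing adoption with instruments z
  drawn i.i.d. standard normal. The default is a single instrument with
  φ = 1, which gives an adoption rate of one half and a strong first stage
  (first-stage R² ≈ 0.5). The indicator uses a strict `>` at zero — a
  measure-zero convention;
* `T = T* + η` — the self report, with η = −1 (false negative) only where
  T* = 1 and η = +1 (false positive) only where T* = 0.

The latent errors (μ, ω, e) are trivariate standard normal with correlations
(σ_μω, σ_μη, σ_ωη) interpreted as *correlations with unit variances*: the
benchmark grid's values all lie in [−0.8, 0.8] and are scale-free.
Construction fails with the offending matrix when the implied correlation
matrix has a negative eigenvalue; sampling uses an eigenvalue factorisation
so positive-*semi*definite boundary cases still work.

**Discretising η.** How a discrete η with target rates arises from a
Gaussian latent is a genuinely open design choice; we threshold the latent
propensity e at its *empirical stratum quantile*: among true adopters, the
`round(fn·n₁)` units with the lowest e become false negatives; among true
non-adopters, the `round(fp·n₀)` units with the highest e become false
positives. This guarantees the realized false-negative/false-positive rates
match their targets for *any* correlation structure (a fixed marginal-normal
cutoff would not, because e is not standard normal within a stratum when
σ_ωη ≠ 0), while η remains correlated with (μ, ω) through the latent
ranking — which is exactly what makes misreporting endogenous.

A consequence worth knowing: with a rank-based mechanism the flips are
(conditionally on the stratum) unrelated to the instrument, so
cov(z, T) = (1 − fn − fp)·cov(z, T*) and the linear 2SLS estimate under
misclassification is *inflated* by 1/(1 − fn − fp) rather than attenuated.
Published simulation tables for this model report attenuated IVs, which
implies a mechanism in which misreporting also depends on the adoption
index; no such mechanism is identifiable from the model equations alone, so
the package treats only the no-misclassification IV cells and the
qualitative OLS patterns (sign reversal, upward bias, attenuation monotone
in fn) as checkable claims. The endogenous-cell OLS magnitudes produced
here are correspondingly larger than those printed tables (e.g. −0.78
rather than −0.36 in the sign-reversal cell).

Optional outcome error: `W = W* + Ψ`, `Ψ = αW* + ν` with ν independent
normal noise (default off). With exogenous adoption this scales the OLS
slope by exactly (1+α).

## 2. Bias formulas (`mistreat.bias_theory`)

`plim_ols` evaluates

```
(1+α) · [δ(σ_T*η + σ²_T*) + σ_T*μ + σ_ημ] / (σ²_T* + 2σ_T*η + σ²_η).
```

On *sample* moments this is algebraically identical to the no-controls OLS
slope of W* on T — the formula is the slope decomposition — and the test
suite checks the identity to 1e−8 on random scenarios. The population
moments mix latent quantities (μ) with observables, so the evaluation is
only defined for simulated data where μ is known.

`plim_iv` has no closed form under the thresholded misclassification
mechanism and is evaluated by simulation at ≥10⁶ draws. The default
(`first_stage="linear"`) returns the limit of the linear 2SLS estimator the
Monte Carlo engine actually uses, `cov(z, W)/cov(z, T)`;
`first_stage="conditional"` implements the conditional-expectation first
stage by quantile-binning the instrument index (200 bins) and returns
`cov(W, Ê[T|z])/var(Ê[T|z])`. With a single Gaussian instrument the two
agree closely; they are both available because the theoretical expression
is written with E[T|z] while common practice (and the engine) uses the
linear projection.

## 3. Estimators (`mistreat.estimators`)

All estimators consume a `RegressionInput` (outcome, treatment, controls,
location labels, instruments, misclassification code, cluster ids) and do
listwise deletion with a reported dropped-row count. Location labels are
expanded to dummies (first level dropped). Rank deficiency is detected by
pivoted QR and reported with the offending column names.

* **OLS** via statsmodels, HC1 robust or CR1 cluster-robust standard errors
  (CR1 = G/(G−1)·(n−1)/(n−k) small-sample scaling at the cluster level, the
  standard econometric default for survey clusters).
* **2SLS** implemented directly (projection of the design on the instrument
  set, sandwich covariance with the same CR1/HC1 scaling). The first-stage
  partial F of the excluded instruments is reported and results are flagged
  weakly identified below F = 10. A just-identified no-controls fit equals
  cov(z,W)/cov(z,T) to 1e−10, and the implementation is cross-checked
  against an independent 2SLS implementation in the test suite.
* **η-control**: the code enters as an exogenous regressor (and as an
  included instrument under 2SLS — the IV-with-η specification instruments
  the treatment only). An all-zero code degenerates gracefully to the plain
  regression with a zero coefficient. The identity
  `coef(T | η) = coef(T* | η)` and the companion
  `θ(T-model) = θ(T*-model) − γ` are exact algebra and tested at 1e−8.
* **Lewbel-style heteroscedasticity IV**: instruments are mean-centered
  continuous regressors times first-stage residuals, with no external
  instruments mixed in. Identification requires cov(x, e²) ≠ 0 — note that
  *symmetric* conditional variance (e.g. proportional to x²) violates this
  even though it is strongly heteroscedastic. A Breusch–Pagan test of the
  first stage is attached; p > 0.1 flags weak identification.
* **Bivariate probit**: recursive two-equation probit with correlated
  Gaussian errors, maximised by BFGS from independent-probit starting
  values with ρ parameterised as tanh (gradient tolerance 1e−6;
  non-convergence raises with the final gradient norm; |ρ̂| > 0.99 sets a
  boundary flag). The bivariate normal CDF uses Owen's T function
  (vectorised, checked against an independent implementation at 1e−8).
  The reported effect is the sample-average treatment effect
  `mean[Φ(x'β̂+γ̂) − Φ(x'β̂)]`; its standard error comes from the inverse
  observed information with a delta method. Cluster-robust inference for
  the bivariate probit is available through the cluster bootstrap rather
  than analytically.
* **Bootstrap**: resamples whole clusters with replacement (relabelling
  resampled clusters so repeats stay distinct), minimum 50 draws, errors
  out if more than 10% of draws fail.

## 4. Monte Carlo engine (`mistreat.mc_engine`)

Per-cell seeds derive deterministically from a master seed and the cell
index (`SeedSequence([master, index])`), so grids can be evaluated in any
order or subset without changing results. Within a cell the no-controls OLS
and just-identified IV estimates are computed in closed form (tested equal
to the matrix estimators at 1e−10); the cell reports arithmetic means and
Monte Carlo standard errors across replicates. The built-in 18-cell grid
covers false-negative rates {0, 0.15, 0.3, 0.47, 0.5}, false-positive rates
{0, 0.05, 0.1, 0.25} and the endogeneity regimes (±0.8, ±0.3, ±0.3) /
(0.01, 0.01, 0.3) / (0.4, ·, ·). Simulation regressions carry no
covariates. The acceptance script runs the benchmark cell at the full 1000
replications of n = 10,000; the test suite uses 200-replication scaled runs
of the same cells, which already pin the means to ±0.005.

## 5. The synthetic survey (`mistreat.survey_synth`)

The generator emulates the *structure* of a DNA-validated adoption survey,
not any particular country's data: 500 enumeration areas (EAs) × 5
households = 2,500 households, 1–4 cassava plots each, household covariates
with realistic marginals (size, education, age, livestock units, land,
assets, access dummies, distances, road quality), EA-level random effects,
and two binary instruments — a consumption-trait preference (59%
prevalence) and EA-level pest incidence (25%) — entering the adoption index
with coefficients 0.8 and 0.6. The adoption intercept is calibrated by root
finding so the expected benchmark household adoption rate is 0.66.

**Misreporting** is decided at the household level by rank-based flipping:
among benchmark adopters the `round(0.19·n₁)` households with the highest
misreport score become false negatives (and analogously 0.15 for false
positives), reproducing the 66% benchmark vs ≈59% self-reported rates.
The score has two loadings chosen to reproduce the two qualitative patterns
validation studies report:

* a *margin* link (−3.0 × the adoption index excluding the welfare
  unobservable): marginal farmers misreport most. This makes the flip
  probabilities instrument-dependent in the direction that *attenuates*
  self-reported IV estimates — without it, rank-based flipping mechanically
  inflates IV (see §1);
* a *wealth* link (+0.7 × the household welfare unobservable for false
  negatives, −0.7 for false positives): false negatives are richer than
  correct non-adopters and false positives poorer than correct adopters.

The margin link must exclude the welfare unobservable because the adoption
index itself contains it: loading on the full index would push the two
links against each other and reverse the wealth ordering.

Plot labels inherit the household decision (a false-negative household
reports all its plots local), then a top-up of within-household flips —
constrained to preserve the household OR-aggregate — brings the *plot*-level
rates to the same 0.19/0.15 targets and creates within-farmer variation.

**Welfare.** Log per-capita total expenditure is linear in benchmark
adoption (true effect 0.35, within the 30–40% range such studies target),
a few covariates, the EA effect, the household unobservable (loading 0.3 —
this is what makes adoption endogenous, as the same unobservable enters the
adoption index with loading 0.35) and N(0, 0.4) noise; the intercept places
roughly 45% of households under the $1.9/day line. Food expenditure is a
Beta-distributed share (mean 0.68) of the total. Food shortage is a probit
in adoption (latent effect −0.8, calibrated to a 63% marginal rate) with
the same unobservable, and the months-short count is built on top of it.

**Consumption modules.** 20 food items (reduced from the 164 of a full
survey for speed; the count is configurable) with EA-level prices around
item base prices. Weekly household food value — `exp(log pc food) × size ×
7/365` — is split across consumed items; each item row is a purchase
(unit value observed) or own-production/gift (quantity only). For 10% of
own/gift rows (configurable) the household has no purchase of the same
item, exercising the median-price imputation path. 10 non-food items carry
monthly values summing to total minus food. Currency units are abstract;
the poverty line is expressed in the same units per capita per day.

**What the generator does *not* emulate:** geographic realism, sampling
weights or PPS mechanics, covariate-dependent misclassification,
item-specific Engel curves, seasonal price variation, or any actual
DNA-marker process. Passing tests therefore demonstrate correctness of the
estimators and pipeline under a *known, well-behaved* error structure —
not that any particular real-world estimate is right.

## 6. Pipeline choices (`mistreat.survey_pipeline`)

* Unit-value imputation ladder: household's own unit value (median over its
  purchases of the item) → EA-level median → survey-wide median → excluded
  with a warning count. The survey-wide fallback mirrors standard LSMS
  practice for thin community price cells.
* Annualisation: 7-day food recall × 365/7; monthly non-food × 12; poverty
  uses annual total / 365 against a strict `< 1.9` threshold (exactly 1.9
  is non-poor).
* Expenditure outcomes are log-transformed; effect sizes of 0.1–0.6 on
  welfare outcomes are only plausible on the log scale.
* Food-shortage coding defaults to 1 = experienced a shortage, which gives
  adoption a negative coefficient; the reverse (1 = food secure) is
  available via `coding="secure"` since questionnaires often phrase the
  item that way.
* "Location dummies" are coarse region dummies (6 regions of EAs), not EA
  dummies: with 5 households per cluster, EA fixed effects would absorb the
  EA-level pest instrument and most degrees of freedom. Standard errors are
  clustered at the EA.
* Plot-level regressions repeat household outcomes and covariates across
  plots, use the plot-level treatment, and cluster at the EA.
* The battery: food shortage via bivariate-probit ATE; log food/total
  expenditure via OLS and 2SLS; poverty via 2SLS with cluster-bootstrap
  standard errors (200 draws by default); each with and without the
  η-control.

## 7. Known limitations

* The Eq.-level misclassification mechanism is not identified by the model;
  quantitative OLS/IV magnitudes in endogenous cells depend on it (§1).
* `plim_ols` needs latent moments and is simulation-only.
* Bivariate-probit standard errors are observed-information, not clustered;
  use the bootstrap when clustering matters.
* The Lewbel estimator requires asymmetric conditional variance; its weak-
  identification flag is a one-sided diagnostic, not a proof of validity.
* Bootstrap draws resample clusters independently; stratification of the
  original design is not mimicked.
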