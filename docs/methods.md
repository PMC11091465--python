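# Methods

## The oxidative balance score

The oxidative balance score (OBS) summarizes a participant's combined
exposure to antioxidant and pro-oxidant diet and lifestyle factors.  The
default roster has 22 components — 17 dietary (pro-oxidants: total fat,
iron, PUFA, SFA, meat; antioxidants: calcium, magnesium, vitamins B6, B12,
C, D, E, total folate, carotenoids, fiber, retinol, vegetables) and 5
lifestyle (pro-oxidants: smoking, alcohol, BMI; antioxidants: tea, physical
activity).  Each component contributes 0, 1 or 2 points, so the total lies
in [0, 44], the dietary sub-score in [0, 34] and the lifestyle sub-score in
[0, 10]; higher means more antioxidant exposure.

Composites are formed before scoring: meat = beef + lamb + pork, vegetable
= raw + cooked vegetables, physical activity = light + moderate + vigorous
weekly MET-minutes.  A missing addend makes the composite missing, and any
missing component score drops the participant (complete-case), tallied in
an exclusion log.

Scoring rules:

* **Tertile components.** Cut-points are the 1/3 and 2/3 sample quantiles
  of non-missing values within each sex stratum, using linear interpolation
  between order statistics (the "type 7" convention — the quantile
  definition is not canonical, so it is pinned for reproducibility).
  Antioxidants score 0 / 1 / 2 from the lowest to the highest tertile;
  pro-oxidants are mirror-scored 2 / 1 / 0.  Interval membership is
  left-closed, right-open (`value >= cut` moves you up); with heavily tied
  data the realized bins can be unequal, which is accepted and reported via
  a warning rather than re-balanced by an invented scheme.
* **Abstention components** (smoking, alcohol, meat).  Non-consumption
  (raw value exactly 0) scores 2.  Consumers are split at the consumer
  median within the stratum: at or below the median scores 1, above it 0.
  This "split consumers into two near-equal groups" reading is one
  interpretation of binomial-style grouping; it is the only one we found
  that yields the documented {0, 1, 2} range with abstainers at 2.

Sex stratification applies to cut-point *estimation* only; the scored
cohort is pooled for all downstream analyses.  The OBS total is then
categorized at its sample quartiles (left-closed right-open, final interval
closed at the observed maximum); fixed edges can be supplied to replicate a
published categorization.

## Survival models

Three nested Cox proportional-hazards models are fitted with years since
study entry as the time scale (age is a covariate, not the clock):

* Model 1: age, ethnicity (indicator contrasts, European reference),
  education score, Townsend deprivation index;
* Model 2: Model 1 + daily dietary energy intake;
* Model 3: Model 2 + plasma CRP + NSAIDs use.

The exposure enters continuously (HR per OBS unit) or as quartile
indicators against Q1.  P-for-trend re-enters the quartile index (1–4) as a
single continuous covariate and reports its Wald p.  Ties are handled with
the Breslow approximation (lifelines' convention).  Fits are complete-case
per model; subgroup analyses refit within the stratum without interaction
terms.  Degenerate problems — no events, a constant exposure, empty
subgroup, non-convergence — return explicit failure results carrying a
message, never silent numbers.  Sparse binary covariate indicators whose
carriers experience no (or only) events are dropped from adjustment sets
before fitting: their coefficients are not identified and they otherwise
drive the likelihood to a boundary.  At desk-scale n this mostly affects
the smallest ethnicity categories.

Sensitivity analyses: the leave-one-out table refits the Model-3 continuous
fit once per component with that component's score removed from the total
(range 0–42, one "OBS without c" row per component), and the sub-score
analysis fits the dietary and lifestyle sub-scores separately.  The percent
risk reduction implied by a hazard ratio is reported as (1 − HR) × 100,
rounded to one decimal.

Biomarker associations (albumin, uric acid, neutrophil count vs the
cumulative CRC flag) use maximum-likelihood logistic regression with the
Model-3 covariate set, continuously and by sex-pooled biomarker quartile.
Using the cumulative event flag discards time-at-risk; it is retained
because odds ratios, not hazards, are the target of that analysis.

## Mediation

For each biomarker M the package fits a linear mediator model
M ~ OBS + covariates and a logistic outcome model Y ~ OBS + M + covariates,
then computes indirect and direct effects on the average risk-difference
scale by the potential-outcomes decomposition

    IE = E[Y(x+1, M(x+1)) − Y(x+1, M(x))],
    DE = E[Y(x+1, M(x)) − Y(x, M(x))],

with the one-unit contrast applied at each participant's observed OBS (so
IE/DE are per-unit quantities, commensurate with the per-unit HRs and ORs;
fixed control/treat levels are available).  Uncertainty is quasi-Bayesian:
parameters are drawn from each fit's asymptotic normal distribution,
mediator values are simulated with the estimated residual SD (shared noise
across counterfactual arms, an antithetic coupling that reduces Monte-Carlo
variance without changing the expectation), and percentile intervals are
taken over the draws.  A nonparametric bootstrap variant exists behind
`method="bootstrap"`.  The risk-difference scale was chosen because
indirect effects of order 10⁻⁴–10⁻⁶ per unit are only interpretable on a
probability scale.

The proportion mediated is IE / (IE + DE) × 100, signed; when IE and the
total disagree in sign the absolute value is reported and flagged.  This is
a proportion of the effect, not "variance explained" — the two are
sometimes conflated in applied reports.  A significant mediating effect is
declared when the IE interval excludes 0 (the sign of a meaningful IE
depends on the path signs: an exposure that lowers a risk-raising mediator
has IE < 0).  Near-zero total effects return an undefined proportion rather
than a division blow-up.

## The synthetic cohort generator

The generator emulates the *structure* of a large UK-Biobank-style
prospective cohort, not its exact marginals (which are not published at the
level needed): one row per participant with demographics, 22 raw exposures,
three serum biomarkers, and time-to-event CRC outcomes by subsite.

* **Exposures** are log-normal within sex, with male median multipliers on
  intake variables; smoking, alcohol and the meat items are zero-inflated
  (a point mass of abstainers plus a log-normal consumer part) so the
  abstention rule is exercised.  Means and dispersions follow the published
  cohort where printed (age 55.9 ± 8.0, BMI 26.9 ± 4.6, energy
  8862.8 ± 3036.6, TDI −1.6 ± 2.9, albumin 45.4 ± 2.6 g/L, uric acid
  306.4 ± 79.1 µmol/L, neutrophils 4.1 ± 1.4 ×10⁹/L, 53.5% female,
  ethnicity shares, per-variable missingness fractions); everything else
  is a documented artifact choice at conventional dietary scales.
* **Causal structure.**  The true OBS is computed by the same scoring rules
  as the analysis.  Mediators are linear in the true OBS plus Gaussian
  noise at the published dispersion.  Each CRC subsite is a competing
  exponential process (Weibull shape exposed in the configuration) whose
  log-hazard is linear in OBS, the mediators and any configured covariate
  effects; the minimum over subsites is censored administratively at 8
  years (entry 2006–2010, exit end-2014).  `beta_obs` entries are *total*
  per-unit effects — the generator backs out the direct piece as
  total − Σ a·b — so an analysis model that omits the mediators targets
  exactly the configured number.  The default CRC total is ln(0.974) per
  OBS unit with a baseline hazard of 0.0019/year (≈1.5% cumulative
  incidence), the scale of the motivating cohort.
* **Complications** (obstruction, abdominal pain, metastasis, CRC death)
  are Bernoulli flags among incident cases at published case fractions,
  with configurable log-odds dependence on OBS (default none).
* **Missingness** is MCAR only (the analysis is complete-case, so MCAR
  suffices to exercise the plumbing); competing risks of non-CRC death are
  not simulated (death is treated as censoring).  Ground truth (true OBS,
  linear predictors, uncensored times) lives in a separate `_truth` table
  keyed by participant id so it cannot leak into analysis code paths.

What passing tests on these cohorts do **not** show: robustness to
informative censoring, FFQ measurement error, non-log-normal exposure
shapes, confounded mediator–outcome paths, or real UK Biobank marginals.

## Validation studies and problem sizes

The package's standard validation scale is n = 20,000 participants
(≈300 events at default conditions), chosen as the smallest size at which
Wald intervals behave nominally for an effect of this magnitude:

* **Cox recovery**: 100 replicates at true HR 0.974/unit; the replicate's
  own 95% CI covers the truth ≥90% of the time and the geometric-mean HR
  sits at the true scale.
* **Null calibration**: 200 replicates at zero true effect; CI coverage of
  1 within 95 ± 4 points and Kolmogorov–Smirnov uniformity of the trend p.
* **Mediation recovery**: a designed single-mediator scenario (uric acid
  carrying 20% of a total log-HR of −0.10/unit, event rate raised to ≈7%
  so the outcome model is well identified) recovered within ±5 points of
  the truth computed by potential-outcomes enumeration on the generating
  model itself; a broken-path (a = 0) scenario yields an IE interval
  covering 0.
* **Determinism**: identical configuration + seed gives byte-identical
  cohorts, tables and manifests; the global seed fans out to per-stage
  child seeds via a seed sequence so stages can be re-run in isolation.

## Known limitations

* The abstention ("binomial grouping") rule is an interpretation; other
  readings (e.g., scoring smoking on pack-years tertiles) would change the
  lifestyle sub-score.
* Complication models use Cox on case-restricted data; a logistic variant
  is available, and neither addresses selection into the case subset.
* Quartile edges are re-estimated per cohort; published fixed edges can be
  supplied but integer scores make exact quartile balance impossible.
* The mediation outcome model is logistic on the cumulative flag; a
  time-to-event mediation model is out of scope.
* No multiple-testing correction is applied anywhere, matching the
  analysis design the package implements.
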