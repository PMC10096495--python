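# Methods

## The estimation problem

The package targets settings where mortality must be reconstructed, not
measured: a crisis-affected population observed only through (i)
retrospective household surveys with 3–4 month recall windows, conducted at
irregular times and places; (ii) routine programme series (conflict events,
severe-acute-malnutrition admissions, epidemic case counts, market prices)
available by district and month; and (iii) several mutually inconsistent
population estimates plus reported displacement movements. The strategy is
small-area estimation: fit a predictive model of the death rate on the
surveys, then apply it to every district-month, multiply by reconstructed
person-time to get tolls, and difference against a counterfactual.

## Survey re-analysis

Each household contributes a death count and person-days at risk within the
recall window. The rate estimator is an intercept-only Poisson GLM with a
log person-time offset, whose MLE is identically `Σ deaths / Σ person-days`
(asserted as a test invariant). Variance uses the CR0 cluster sandwich —
no small-sample correction, clustered on survey cluster, each household its
own cluster under systematic sampling — chosen so results are reproducible
bit for bit; confidence intervals are normal-quantile on the log scale and
exponentiated. Zero-death surveys report rate 0 with the one-sided exact
Poisson upper bound `−ln(α)/PT`.

Aggregate (pre-2016-style) questionnaires record only end-of-recall
membership and event counts. Person-time is reconstructed under a
**mid-period convention**: members with unknown entry/exit dates count half
the recall window, giving
`person_days = recall × [N_end + ½(deaths + leaves − births − joins)]`.
This is a stated convention, not a reconstruction of any particular field
practice; it is exact when events are uniform in time.

The survey quality score is a simplified 0–1 checklist (metadata
completeness, plausible household size, plausible CDR, plausible under-5
share). It feeds reporting only — never weighting — because the full
SMART plausibility score requires anthropometric data that are out of scope.

## Population denominators

With monthly growth factor `g = (1 + r)^(1/12)` (default r = 2.1%/yr),
forward projection is `P[t+1] = g·P[t] + netflow[t+1]` and backward
projection its exact algebraic inverse, so round trips are lossless (a test
covers a 74-district × 60-month grid at < 1e-6 relative error). Net flow is
applied after growth within a month — an order the data cannot identify,
fixed here for reproducibility. Series are floored at 1 person; the floor
binding is a data-quality warning, since it means reported flows exceed the
projected stock. Sources are combined by quality-weighted arithmetic mean;
under-5 populations apply a single global fraction (default 0.250).
Incident displacement before 2016 is zero by assumption, mirroring the
availability of monitoring-network data only from 2016 onward.

## Predictor panel

A predictor is retained when at least 70% of district-months are observed
(inclusive); composite predictors additionally require each sub-series to be
≥ 70% complete. Missing district values are imputed monthly by a spatially
weighted mean (same region weight 1.0, elsewhere 0.3 — weights that are
conventional, not estimated). Price series are then smoothed with a
penalized cubic spline; the 0–1 smoothness knob maps to the roughness
penalty `λ = 10^(6s − 2)` on the month-index scale, a monotone map chosen so
the default s = 0.3 gives mild smoothing; exact replication of any
particular spline library's parameterization is deliberately not promised.
Counts become rates per 100,000 via the reconstructed denominators. Lags up
to 6 months shift within districts. Categorical encodings use
lower-inclusive half-open intervals (0.25 falls in "0.25 to 0.49", 0.50 in
"≥ 0.50"); the SAM admission cut-points {100, 200} per 100,000
person-months are a package default, flagged as such because the source
material for that predictor's levels is internally inconsistent. Recall-
window averaging is day-weighted over the overlapped calendar months and
happens **before** categorization, matching the continuous-then-cut order of
the model terms.

## Model fitting and selection

Household deaths are quasi-Poisson: Poisson score equations (point estimates
identical to the Poisson MLE), dispersion `φ = Pearson χ²/df`, and CR0
cluster-sandwich covariance. Degenerate category levels in sparse survey
draws are handled explicitly: a level never observed in training is treated
as reference (coefficient 0, zero variance, warning), and when a term's
reference level itself never occurs, the lowest observed level is merged
into it. Structural rank deficiency (duplicated terms) still raises.

Model search: single-term screening against the intercept-only model
(margin 0), then brute-force enumeration of all term subsets (capped at
4,096), ranked by the mean Dawid–Sebastiani score over 10 cross-validation
folds. `DSS = (y − μ)²/σ² + log σ²` with predictive variance `σ² = φμ` —
the quasi-Poisson-consistent choice — and `μ` floored at 1e-12 to keep the
log finite for degenerate predictions. Folds partition **surveys**, never
households, so cluster structure cannot leak across folds; held-out
households are scored with the training fold's φ. The top 20% (ceiling) of
the ranking is re-scored on an 80/20 survey-level holdout; the shipped
final-choice rule — lowest holdout score, then fewest parameters, then
lexicographic key — is deterministic and recorded in the run manifest,
standing in for what is, in real analyses of this kind, a documented manual
choice. Random effects and interactions are deliberately outside the search
space. Under-5 models reuse the specification selected for the crude rate,
so both age groups arise from one statistical process.

## Counterfactuals and excess

Scenario rules operate from the excess window onward (default January
2017): month-specific statistics replace the value at (district, calendar
month, year ≥ 2017) with the median/p25/p75 of the same calendar month in
2014–2016 within the district, falling back to the region when a district
lacks reference data; fraction rules scale actuality; "zero" removes the
exposure; displacement rules filter the flow table (drop drought-tagged
flows, drop all new flows, or keep actuality) before denominators are
rebuilt. One caveat documented here: with positive SAM and conflict rate
ratios, the shipped "worst case" rules (p75 SAM, actual conflict/measles,
quartered malaria) produce a *higher* counterfactual — hence smaller
excess — than the most-likely scenario on synthetic data; the scenario
labels follow the source convention rather than the induced ordering, and
quantitative validation uses the unambiguous most-likely scenario.

Expected deaths are `exp(x'β) × population × days-in-month`. The bootstrap
draws `β ~ N(β̂, Σ̂)` (eigenvalue-clipped if Σ̂ is numerically indefinite,
logged) and applies the **same draw to both arms** of each replicate, so an
identity counterfactual yields exactly zero excess in every replicate — an
acceptance-tested identity. Interpreting "model error" as coefficient
uncertainty only, excluding Poisson realization noise, is the single most
consequential interpretation in the package: the target is the *expected*
excess toll, not a predictive draw. Modes use the Freedman–Diaconis
histogram (midpoint of the modal bin; degenerate distributions return the
common value); intervals are empirical 2.5/97.5 percentiles with linear
interpolation; district and monthly replicates are summed before
summarizing, so per-replicate additivity holds exactly while the national
mode need not equal the sum of district modes. Report tables round half-up
to the nearest 100.

## Sensitivity analyses

The bias grid multiplies census anchors and/or flow counts, rebuilds
denominators and re-estimates excess with the rate model held fixed; the
identity cell (1.0, 1.0) reproduces the baseline bit for bit under equal
seeds. Under-reporting analysis inverts `observed = (1 − p) × true` to get
`unseen = round(observed × p/(1 − p))` (banker's rounding, documented), then
re-attributes the unseen under-5 deaths multinomially across households with
probability proportional to under-5 person-time — person-time weighting is
a package choice where uniform weighting would also have been defensible —
and **refits** the model per replicate before recomputing excess. One
consequence of survey-level covariates is worth knowing: the Poisson point
estimates depend on the data only through per-survey death totals, so the
within-survey allocation of unseen deaths moves the robust covariance but
not the point predictions — replicate variability in the excess point
estimate is therefore tiny, and modest R suffices when only point
predictions are tracked.

## The synthetic world

The generator is the package's test bed and defines its study conditions.
Defaults: 12 districts in 4 regions over 2014-01..2018-12; reference-
stratum rates 0.43 (CDR) and 0.66 (U5DR) per 10,000 person-days; household
size 1 + Poisson(4.6) (mean 5.6); under-5 membership Binomial(size, 0.25);
cluster surveys of 30 × 15 households with 80–120 day recall; growth
2.1%/yr; four census anchors with one multiplicative bias each drawn from
±15%; a 2017-01..2018-06 crisis window that roughly doubles conflict and
SAM-admission rates, halves facility malaria, raises measles-outbreak
probability to 0.35 and generates drought-tagged displacement with a
reason mix near 55/30/12/3%. True log death rates are
`log(baseline) + Σ coefficient × encoded term`, using the *same* cut-points,
lags and dummies as fitted models; the default coefficient map is the
published final-model rate-ratio set, so parameter-recovery studies target
known printed values. Surveys draw household deaths as Poisson with
expectation rate × person-time, splitting under-5 and over-5 components via
the composition identity `CDR = f·U5DR + (1 − f)·rate_5+`, which makes the
pooled estimators exactly unbiased. Between-cluster heterogeneity is an
optional lognormal frailty (mean 1, default variance 0) — a positivity-
preserving choice where the generative truth is genuinely unknown.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: measurement error in the four model
predictors (they are observed exactly; only the price series carries
missingness and noise, which is what the imputation/smoothing stages
exercise), livelihood-zone/district frame mismatch, migration event streams
within households (members are present for the whole recall window by
default, so aggregate-questionnaire re-analysis carries a ≲ 0.5% rate bias
from the mid-period convention), real geography, and any spatial
correlation beyond region labels. Predictor values are emitted directly as
per-100,000 rates; the count-to-rate step is exercised separately.

## Numerical conventions, at a glance

| choice | value |
| --- | --- |
| sandwich estimator | CR0, clustered on survey cluster |
| CI quantiles | normal (z = 1.96), log scale |
| DSS predictive variance | φμ, μ floored at 1e-12 |
| CV unit / folds | surveys / 10 |
| shortlist | ceiling of 20% of ranked models |
| final-model rule | lowest holdout DSS, then fewest parameters |
| bootstrap | coefficient MVN only, same draw both arms |
| mode | Freedman–Diaconis modal-bin midpoint |
| percentiles | linear interpolation |
| table rounding | half-up to nearest 100 |
| unseen-death rounding | half-even |
| seed fan-out | SHA-256(master:stage) mod 2³¹ |

Problem sizes in the test suite (12 districts, 30–50 surveys, B = 500–1,000,
100–200 Monte-Carlo replications) are the package's chosen desk-scale study
conditions; the acceptance script runs the full B = 10,000 bootstrap.

## Known limitations

Coefficient-only uncertainty understates total uncertainty where dispersion
or denominator error dominates (the bias grid quantifies the latter
separately). The CR0 sandwich is mildly anti-conservative with few
clusters. Counterfactual validity rests on the scenario rules, which are
assumptions, not estimates; the month-specific reference statistics need at
least one reference-year observation per district (region fallback
otherwise). The brute-force search is exponential in the candidate count
and intentionally capped.
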