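# Methods

## The model

`dlbclsim` is a patient-level discrete-event simulation of the treatment
pathway for diffuse large B-cell lymphoma (DLBCL). Each simulated patient
receives fixed attributes at diagnosis — age (a Beta(3.73, 2.32) draw scaled
to 18–100 years, mean ≈ 68.6), sex (age-banded male proportion), and a
diagnostic category (Stage IA / CNS involvement / standard / died before
diagnosis) — and is then moved from event to event; time advances by sampled
inter-event durations, not fixed cycles.

The pathway splits at diagnosis into a curative-intent branch and a
palliative branch. Palliative patients draw a single end-of-life duration
and die. Curative patients wait a diagnosis-to-treatment interval, then
enter first-line chemotherapy: a regimen and cycle count are drawn from the
line- and category-specific mix, a time-in-treatment is drawn, and one of
three outcomes follows — died during treatment, response, or no response.
Responders draw a composite time-in-response-to-exit; if that time reaches
the cure threshold (5 years of sustained remission) the exit is cancelled,
the patient is cured, disease-related costs stop, and mortality reverts to
the general-population life table. Otherwise the exit is classified relapse
or death-in-remission by a context node. Relapsed and refractory patients
face age-banded re-treatment decisions; second-line treatment may include an
autologous stem-cell transplant (ASCT); lines beyond the third reuse
third-line behaviour (the decision probabilities for those rows are stored
with an explicit `assumed_same_as_line2` provenance flag, matching their
published footnote). Patients not re-treated enter end-of-life care.

Horizons: 5-year, 15-year, or lifetime (simulation until age 100 or death).
Note a structural consequence: for patients diagnosed after age 85 the
lifetime horizon is *shorter* than 15 years, so horizon monotonicity of mean
cost holds exactly only for 5y→15y and in aggregate for 15y→lifetime.

## Time-to-event kernel

Five parametric families are supported — exponential, Weibull, log-normal,
log-logistic, Gompertz — in the parameterisations tabulated in
`dists.py`'s module docstring (one table, used everywhere, to avoid dialect
drift). Gompertz uses hazard h(t) = rate·e^(shape·t) with shape ≥ 0 enforced
so that S(t) → 0. Sampling is by inverse CDF; every stochastic operation
takes an explicit generator or seed (no hidden global state). The internal
time unit is days; conversions use 365.25 days/year.

Background mortality after cure is drawn from a life table of annual death
probabilities qx by sequential Bernoulli trials over years of age, the first
(fractional) year scaled by the remaining fraction, and the within-year
death time drawn uniformly — the within-year convention is this package's
choice, as the source material does not specify one.

## Fitting

`survfit` maximises the right-censored log-likelihood
Σ_events log f(t) + Σ_censored log S(t) over an unconstrained
reparameterisation (log of positive parameters, identity for the lognormal
location), starting from method-of-moments values, with a Nelder–Mead pass
polished by BFGS. The coefficient covariance is the inverse
finite-difference observed information at the optimum, projected onto the
positive-semidefinite cone, on the same unconstrained scale the PSA draws
use. Covariates enter through a log-linear link on the scale-like parameter
(accelerated-failure-time style for Weibull/log-logistic/log-normal,
proportional-hazards style for exponential/Gompertz); the link choice is a
package decision, documented here because the source presents only "best fit
distributions as a function of patient's age, treatment intent and treatment
details". Family selection minimises AIC = 2k − 2·loglik, ties broken toward
fewer parameters, then list order. Fits with fewer events than parameters
are refused rather than silently returned at a boundary. Cross-checks
against lifelines' Weibull and log-normal fitters (agreement to 0.1%) are in
the test suite; the in-house implementation exists because Gompertz and the
unified covariate link are not jointly available there.

## Costs and discounting

All amounts are GBP 2013. Each cash flow is booked at its event time and
discounted by (1.035)^(−t years); a discrete-event model has no cycles, so
no half-cycle correction is applied. Chemotherapy is costed per cycle at
evenly spaced times across the time in treatment; phase support bundles
(inpatient spells, excess bed days, outpatient attendances) and one-off
extras (radiotherapy for Stage IA, high-dose methotrexate with IDARAM, the
£42,000 ASCT) are booked at phase start. Follow-up visits during response
run quarterly for three years then annually, stopping at exit, cure or
horizon. Life-days are accumulated undiscounted and as the analytic
integral of the discount factor over alive time; both are reported because
it is ambiguous whether the published life-day columns are fully
discounted.

Costing phases mirror the published breakdown (diagnosis; line 1; line 2
with/without ASCT; line 3; follow-up in first/second response; end-of-life
split by prior treatment). Totals are exactly additive over phases, and the
whole cost surface is linear in unit costs — both are tested invariants.
Patients in the "died before diagnosis" category accrue the diagnosis
bundle only and are counted in the not-treated stratum so that strata
partition the cohort; the ledger keeps phases separate so either
total-cost convention (with or without the diagnosis bundle) can be
reported.

## Parameterisation and its provenance

`table_params.yaml` holds the published headline parameterisation verbatim:
age-banded decision nodes with Beta/Dirichlet hyperparameters, the unit-cost
table, and model constants (3.5% discounting, 5-year cure threshold, age-100
cap, 4880 expected annual UK cases, 500 PSA iterations, 10-year prevalence
burn-in). Base-case runs use the printed point estimates; hyperparameters
drive only PSA draws, because several printed proportions differ from the
hyperparameter means (e.g. 0.96 vs 39/41 = 0.951) — the point estimates are
empirical proportions, the hyperparameters encode uncertainty. A zero alpha
or beta is a point mass at 0 or 1 in both base case and PSA.

Everything the headline tables do not print — treatment-outcome
probabilities, regimen mix and cycle distributions, time-to-event
coefficients, costing bundles, the follow-up schedule — lives in
`esm_params.yaml`, flagged `provenance: synthetic_calibration`. Those values
were set once, by inverting the published aggregates (stratum patient
counts, per-phase mean costs and durations), and are deliberately kept in a
separate file so the verbatim parameterisation is never silently mixed with
reconstruction. Users with access to the full supplementary coefficient
tables can override either file key-by-key. The packaged life table is a
synthetic Gompertz–Makeham construction calibrated to published UK 2011–13
period life expectancies (male e0 79.1, e65 18.5; female e0 82.9, e65 21.0)
and is named accordingly.

## Uncertainty

The probabilistic sensitivity analysis redraws every decision-node
probability from its Beta/Dirichlet, every time-to-event coefficient vector
from a multivariate normal on the unconstrained scale (variances from the
fitted information or the configured `vcov`), holds unit costs fixed, and
re-simulates a fresh cohort per iteration; stratum means across iterations
yield 2.5/97.5-percentile intervals. Seeds derive from a single master
`SeedSequence`, so intervals are exactly reproducible. The configured
default is 500 iterations; at the full cohort size of 4880 this is an
overnight-scale pure-Python run, so the test suite and the acceptance
script exercise the PSA machinery at reduced sizes and the full setting is
left to the CLI (`dlbclsim psa --iterations 500`).

## Prevalence accounting

The prevalence analysis staggers one incident cohort per simulated year
(diagnoses spread uniformly within the year), books every discounted cash
flow in the calendar year it occurs, discards a 10-year burn-in, and sums
across coexisting cohorts. Because disease-related costs stop at cure,
steady state is reached well within the burn-in, and the annual total obeys
the renewal identity annual_n × mean lifetime cost per patient (a tested
±5% invariant). Reported bounds are the min/max over post-burn-in collection
years — a package convention, since the source does not define its bounds.
A `sim_annual_n` option simulates fewer patients per year and rescales
linearly (the model is linear in cohort size; also tested).

## Synthetic registry and what passing tests show

`synthcohort` emulates the statistical structure of the five-year-follow-up
registry that parameterised the original model: one row per patient,
per-transition durations with event flags, administrative censoring at five
years (non-informative by construction). The registry schema is this
package's design; the real registry's row format is not public. Recovery
experiments refit every transition and compare against the generating
manifest; the end-to-end closure property (simulate → registry → refit →
re-simulate) reproduces mean cost and survival within 5% at n = 10,000.

Passing these tests shows the estimation and simulation machinery is
self-consistent under the model's own assumptions. It does not show the
placeholder parameterisation equals the unpublished one, nor that real
registry data satisfy the parametric families, proportional regimen mixes,
or non-informative censoring the generator imposes.

## Numerical choices and problem sizes

Optimiser tolerances: Nelder–Mead xatol 1e-8/fatol 1e-10, BFGS gtol 1e-8.
AIC ties are resolved at 1e-9 resolution toward parsimony. Degenerate
inputs (all-censored samples, single events, empty strata, a cut that
empties an age group) raise or report explicitly rather than returning
silent numbers. Cohort sizes in the shipped tests and the acceptance script
(600–10,000 patients; prevalence at 1600 simulated patients/year rescaled
to 4880; PSA at 3–12 iterations in tests) were chosen as the smallest sizes
at which the tested invariants' tolerances are comfortably dominated by the
effect under test rather than Monte Carlo noise; the full published sizes
(4880, 500 iterations) remain the configured defaults.

## Known limitations

Quality-adjusted life years are out of scope (no utility data exists for
this cohort); therapy-induced comorbidity costs are excluded; administrative
censoring correction is not attempted (censoring is non-informative here by
construction); regimen-level cost-effectiveness comparisons are not a goal.
Performance status, a stronger survival discriminator than age, is not a
model input. The placeholder blocks make absolute cost/survival magnitudes
indicative rather than definitive; orderings, invariances and uncertainty
machinery are the tested surface.
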