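# Methods

This note documents the statistical models implemented in `cvburden`,
the synthetic-cohort generator used to validate them, the numerical
choices, and the known limitations.

## The estimation problem

In a secondary-prevention population, new adverse events — myocardial
infarction (MI), nonhemorrhagic stroke, urgent and nonurgent coronary
revascularization (CRV), heart-failure (HF) admission, noncoronary
revascularization, incident cancer, incident diabetes, and vascular or
nonvascular death — affect two quantities that drive cost-effectiveness
models: health-related quality of life (EQ-5D-5L utility) and annual
hospital costs. The package estimates, for each event type, the change
in each quantity in the year of the event and in later years, relative
to not experiencing the event.

### Temporal event-history covariates

Both outcome models share one covariate construction: for each event
type, a mutually exclusive and exhaustive indicator of time since the
qualifying occurrence — no event, ≤1 year, 1–2 years, 2–3 years,
>3 years — but the clock differs:

* **QoL** uses the *last* occurrence before the end-of-study QoL
  measurement (recent events dominate current health state);
* **costs** use the *first* occurrence relative to each annual
  follow-up period (periods are days [365.25·k, 365.25·(k+1))).

A year is 365.25 days; the ≤1-year bin is closed on the right (a gap of
exactly one year is still "within 1 year"), and an event on the
measurement day itself counts as the event year. Events are *fatal*
when death falls in the same annual period.

### QoL model

Final-visit utility is modelled by OLS (Gaussian GLM, identity link) on
participant characteristics, the temporal categories of the event types
with detectable QoL effects (stroke, HF admission, noncoronary
revascularization, incident cancer), and — in the main analysis — the
participant's baseline utility, centred at its sample mean. Age is
centred at 67 years and the covariate coding places the modal patient
(male, prior MI only, lowest risk-factor categories) at the reference,
so the fitted intercept is directly the expected utility of that
reference patient at average baseline QoL. Classical OLS standard
errors are used (one row per participant); cluster-robust errors are
available behind a flag. Participants who died before the final visit
or did not complete it are excluded, with counts logged.

### Two-part cost model

Annual hospital costs mix a large mass at zero (~80% of person-years)
with a heavily right-skewed positive part, so they are modelled in two
parts:

1. **Part 1** — logistic regression for the probability of any cost in
   a person-year. Periods containing an urgent/nonurgent CRV or HF
   admission are *certain admissions* (the event itself is an inpatient
   stay): those rows are excluded from part 1 and their probability
   fixed at 1.
2. **Part 2** — a GLM for cost magnitude on positive-cost rows. The
   default family/link is gamma/identity, the specification favoured by
   the specification search on data of this shape (see below).

Both parts share the design (covariates + temporal categories of all
ten event types + any same-year interactions); standard errors are
cluster-robust by participant, since a participant contributes several
annual periods.

Identity-link gamma likelihoods are only defined while every fitted
mean is positive, and the unguarded IRLS routinely steps outside that
region. The solver therefore starts from an identity-link Gaussian
(OLS) fit and takes step-halved Fisher-scoring steps, halving whenever
a step would produce a non-positive mean or increase the deviance. The
logistic part uses an analogous step-halved Newton solver with a
deviance-based stopping rule, which stays finite under the
quasi-separation that rare event-year indicators can induce in small
samples. In (re)samples where distinct indicators coincide exactly —
e.g. when every urgent-CRV participant also had a same-day MI — the
collinear columns are dropped (logged) and the shared effect loads on
the retained column.

### Model-building procedures

All testing uses the 1% significance level.

* **Specification search** (`compare_specifications`): candidates are
  one-part and two-part GLMs over Gaussian/Poisson/gamma families and
  identity/log links. Family appropriateness is judged by the modified
  Park test — a Poisson-QMLE regression of squared residuals on the log
  fitted mean, whose slope estimates the variance power (0 Gaussian, 1
  Poisson, 2 gamma); the link by a Pregibon-style test (significance of
  the squared linear predictor). Admissible candidates (Park slope
  within 0.5 of the family's power, link test not rejected) are ranked
  by RMSE of predicted versus observed cost; AIC/BIC and MAE are
  reported alongside.
* **Covariate selection** (`select_covariates`): backward elimination
  on whole blocks (a categorical variable's dummies are tested jointly
  by Wald F-test, cluster-robust for the cost model), dropping the
  least significant block with p ≥ 0.01 and refitting, followed by a
  forward re-check pass over everything dropped. Age and sex are always
  retained. Event-history blocks take part in the search.
* **Temporal-category merging** (`merge_temporal_categories`): starting
  from the most distant adjacent pair (>3y vs 2–3y) and moving toward
  the event year, adjacent categories whose coefficients do not differ
  (F-test, p ≥ 0.01) are combined into one indicator and the model
  refitted; the sweep stops at the first significant difference. The
  event-year category never merges into the no-event reference.
* **Interactions** (`add_interactions`): for event pairs whose
  same-period co-occurrences exceed 5% of their combined event count, a
  same-year product indicator is tested and retained if significant.
  Under the packaged defaults only MI × urgent CRV clears the bar
  (about half of MIs are treated with a same-day urgent CRV).

### Recycled predictions and cluster bootstrap

The additional annual cost of an event × time category is a marginal
quantity: for every analysis row, expected cost p̂·μ̂ is predicted with
the target category switched on and with it set to no-event, holding
everything else at observed values, and the row-wise differences are
averaged. Switching on a certain-admission event year forces p̂ = 1 for
that scenario; switching it off restores the modelled probability. The
reference scenario only alters the target event's categories — other
events stay as observed — so the estimand is the *additional* cost of
that event. Combination scenarios (MI with urgent CRV in the same
year) switch both categories on, including the interaction term.

Uncertainty comes from a percentile cluster bootstrap: participants are
resampled with replacement (all their person-years travel together,
duplicated participants become distinct clusters), both parts are
refitted with the fixed final specification, and the increments are
recomputed; the SE is the SD over resamples and the 95% CI the
2.5/97.5 percentiles. 1000 resamples by default. Resamples with no
positive costs are redrawn (counted and logged). QoL decrements need no
bootstrap: they are model coefficients with closed-form covariance.

## The synthetic cohort generator

The generator emulates the structure of a large secondary-prevention
trial cohort: 21 820 participants aged 50+ recruited in the UK, other
Europe and North America, followed for 4 years, with the published
baseline covariate marginals, event cumulative incidences (e.g. MI
4.5%, incident cancer 7.4%, death 7.6%), ~88.5% completing both EQ-5D
measurements, hospital costs in ~20% of person-years and mean annual
costs of £607 / $2114.

Generating process, in order:

1. **Covariates** are drawn independently from the published marginals
   (age: truncated normal, mean 67.09, SD 8.3, floor 50). A numeric BMI
   consistent with its category carries the printed missingness (0.2%)
   to exercise the imputation rule (cell means by sex × smoking ×
   randomization arm).
2. **Follow-up and death**: everyone has a nominal 4.0 years;
   competing vascular/nonvascular death (rates 708 and 960 per 21 820)
   truncates follow-up at a uniform day. An optional jitter produces
   staggered partial final years; it is off by default, so partial
   periods arise only from deaths.
3. **Baseline utility** is a mixture of a full-health point mass and a
   truncated normal, matched to the published mean (0.84 UK / 0.88 US).
4. **Events**: each nonfatal type occurs with its configured cumulative
   incidence, at a day uniform on the participant's at-risk window;
   nonfatal types may recur once (15%), which moves the last-occurrence
   clock but not the first-occurrence clock. Incident diabetes is drawn
   only among participants without baseline diabetes. Event rates are
   tilted by a frailty factor exp(κ·(mean baseline utility − baseline
   utility)) with κ = 1: participants in worse baseline health have
   more events. Couplings add same-day triggered events — by default an
   urgent CRV accompanies an MI with probability 482/989, reproducing
   the observed co-occurrence. Deaths are appended as event types.
5. **Costs** follow the two-part generating model: a logit for any
   cost (forced to 1 in certain-admission periods) and a gamma
   (shape 0.5 — SD greater than the mean, matching the published
   £607/SD £2402) around an identity-link conditional mean, per costing
   perspective. One unit-mean gamma draw is shared across perspectives,
   since the same admissions are costed under both conventions. In
   partial periods the non-event baseline mean scales with exposure
   (event-year effects are incurred in full — an admission's cost does
   not pro-rate), floored at a nominal 25 currency units so that an
   incurred admission is never free under either convention (degenerate
   all-zero configurations keep a zero mean and zero costs).
6. **Final utility** is the QoL linear model (reference-patient
   intercept, covariate effects, event-category decrements on the
   last-occurrence clock, 0.6 × centred baseline utility) plus
   N(0, 0.17) noise, generated for survivors; 4.1% of survivors miss
   the final visit, reproducing the 88.5% inclusion rate.
7. **Profiles**: baseline and final EQ-5D-5L profiles are the grid
   profiles whose tariff score is nearest the generated utility
   (lexicographically smallest on ties), under the bundled synthetic
   tariff by default.

### Calibration of the generating coefficients

The QoL generating coefficients are taken directly from the published
final model (e.g. reference utility 0.929 UK, HF-admission event-year
decrement −0.072, stroke −0.067); since OLS is unbiased for a correctly
specified linear model, refitting recovers them without further tuning.

The cost side is harder: the published quantities are *marginal*
increments, which depend on the whole covariate and event-history
distribution through the logistic part. `calibration.calibrate_cost_truth`
therefore solves the part-2 coefficients numerically on a large
reference design (n = 40 000, fixed internal seed): the part-1
intercept is solved for the 20% any-cost share; each event
coefficient solves the linear equation that its model-implied recycled
increment equal the published value; the part-2 intercept matches the
published mean annual cost; and the US same-year MI × urgent-CRV
interaction is solved from the published combination increment
($24 722). A few fixed-point rounds converge to printed precision; the
solved values are frozen as the packaged defaults and re-verified on
fresh designs to ≲0.2%. Because marginal increments are diluted
through probabilities below 1, the conditional-scale coefficients are
systematically larger than the printed increments; that is the correct
inverse mapping. The UK truth has no MI × CRV interaction (it was
detected in US costs only), so UK combination costs are approximately
additive by construction.

### What the generator does and does not emulate

It reproduces the marginals, incidences, co-occurrence structure,
zero-mass and skewness of the real cohort, the exclusion mechanism for
the QoL sample, and a frailty channel that makes the baseline-QoL
adjustment consequential (omitting it inflates event decrements, as in
the real sensitivity analysis). It does **not** emulate: correlation
between covariates (they are drawn independently); event risk depending
on covariates; death risk depending on events (fatal-event frequencies
are not calibrated); the ceiling/censoring of observed utilities (the
generated utility is a latent linear outcome, and the QoL model in
simulate mode fits that latent value — round-tripping through profiles
would censor at 1.0 and bias recovery of published coefficients that
already embed the real ceiling); within-year cost timing; or outpatient
and primary-care costs. Passing recovery tests therefore demonstrates
the correctness of the estimation machinery under the stated generating
model, not robustness to the misspecifications real data contain.

One oddity inherited from the published baseline table: the eGFR
distribution is printed as 85.7% below 45 mL/min/1.73 m² and 9.7% at
≥60, which is implausible for this population and looks like a
mislabelled row. The defaults follow the printed categories; users can
override `covariate_dist["gfr_cat"]`.

## Numerical choices and degenerate inputs

* Positive-mean safeguard: identity-link gamma steps are halved until
  the mean is positive and the deviance non-increasing; convergence is
  declared when the relative deviance improvement falls below 1e-9.
* Logistic fits stop on relative deviance improvement < 1e-10, which
  terminates cleanly under quasi-separation (coefficients stay finite;
  predicted probabilities approach 0/1).
* Exactly collinear or all-zero design columns are dropped (logged) in
  the cost model; the QoL model raises an error naming the collinear
  columns, since its fixed design should never be deficient.
* Ties in profile inversion break to the lexicographically smallest
  profile; out-of-range utilities clip to the tariff's extremes.
* Degenerate generator configurations (all event rates zero, zero cost
  coefficients) produce all-zero costs and all-no-event categories.
* Bootstrap resamples with no positive costs are redrawn, up to a
  budget of 50 extra draws.

## Problem sizes used in validation

The test suite fits the QoL model at the full cohort size (n = 21 820,
20 replicates) and runs the bootstrap-based cost-recovery checks on
cohorts of n = 10 000 with 200 bootstrap resamples, both costing
perspectives sharing each replicate's resample stream.  The size was
chosen because percentile-bootstrap coverage of the cost increments
degrades on much smaller cohorts: the interval width tracks the
heavy-tailed point estimate multiplicatively, so unlucky low draws get
narrow intervals; at n = 10 000 the relative estimator SD is small
enough for coverage to sit near its nominal level. The acceptance script
averages each reported quantity over 5 replicate cohorts at the full
size (per-replicate estimator SDs are ~£335 for the UK event-year
increment and ~$1 620 for the US combination increment).

## Limitations

* The bundled tariff is synthetic: monotone, plausibly weighted, but
  not a licensed national value set. Real analyses must supply the UK
  (EEPRU), US or Chinese EQ-5D-5L coefficients as a CSV.
* Death-related interaction structure (e.g. the much lower cost of a
  fatal MI) is not in the default generating truth; fatal-event
  increments from the defaults are therefore not comparable to
  published fatal-event rows.
* The exposure treatment of death years (baseline scaled, event effects
  in full) is a modelling choice; fitted death-year coefficients absorb
  whatever truncation it leaves unexplained.
* Percentile bootstrap CIs are reported; the published analysis did not
  state its bootstrap CI construction.
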