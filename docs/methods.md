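# Methods

`renalccw` emulates a target trial of early versus delayed initiation of renal
replacement therapy (RRT) in ICU patients with acute kidney injury (AKI),
using the clone–censor–weight (CCW) design, and ships a synthetic ICU cohort
generator with exact counterfactual ground truth so that every estimator in
the pipeline can be validated against a known answer. This note records the
model, the estimators, the design choices that were genuinely open, and what
the synthetic validation does and does not establish.

## The emulated trial

**Eligibility.** Subjects qualify at the first hour (on an hourly grid, no
interpolation) at which all of the following hold, within a 72-hour window
from ICU admission: creatinine-based KDIGO stage at least the trial's minimum
(stage ≥ 1 for the broad trial, stage 3 for the severe trial), respiratory
rate > 10 breaths/min at that hour, at least 12 h of hospitalization before
time zero, still in the ICU, alive, RRT-naive, no chronic kidney disease,
full code status, and an ICU episode of at least 72 h. That hour is time
zero. Exclusion reasons are tallied hierarchically in a fixed order so the
tally always sums to the number excluded.

**KDIGO staging** uses the creatinine criterion only: stage 1 at ≥ 1.5×
baseline or an absolute rise ≥ 0.3 mg/dL within a trailing 48-h window,
stage 2 at ≥ 2.0×, stage 3 at ≥ 3.0× or creatinine ≥ 4.0 mg/dL. Baseline
creatinine is the first recorded value (the record is silent on pre-admission
values). Staging never consults RRT receipt.

**Strategies and cloning.** At time zero each eligible subject is duplicated
into two clones: *initiate within the 72-h grace period* and *never
initiate*. Hourly checkpoints censor a clone at its first protocol
deviation: the never clone at the hour RRT actually begins (at any hour of
follow-up), the early clone at the end of grace if RRT has not begun. Deaths
during the grace period are events in every clone still at risk, and a death
falling exactly on a censoring hour counts as the event (censoring never
erases a grace-period death). Follow-up is administratively censored at the
30- or 90-day horizon; hospital discharge does not censor mortality
follow-up. Time zero is eligibility, not ICU admission.

## Weights

Artificial censoring is informative — sicker subjects initiate earlier — so
person-time is reweighted.

*Treatment-hazard model.* A pooled discrete-time logistic model of
P(initiate RRT in hour *t* | not yet initiated, covariates) over subject-hours
1..72 since eligibility. Covariates: hours since eligibility as a natural
cubic spline (three internal knots at the quartiles of the at-risk hours),
hours from ICU admission to eligibility, age, sex, Charlson comorbidity
index, SOFA, heart rate, respiratory rate, diastolic blood pressure, SpO2,
sepsis, and vasoactive drug use — time-varying fields read at the start of
each interval. A numerator model with the time spline only provides
stabilization.

*Person-time weights (Cox).* Each clone-hour receives the cumulative product
of numerator/denominator probabilities of the adherence it displayed —
(1 − p) ratios while untreated, the p ratio at the initiation hour in the
early arm — frozen once the strategy is resolved (early arm after
initiation, both arms at the end of grace; a never clone deviating after
grace is censored unweighted). Weights are truncated at the 1st/99th
percentiles of the clone-hour distribution by default; an untruncated
summary is always available from the person-time table.

*Adherence propensities (AIPW, balance).* The fixed-horizon estimator needs
per-clone aggregate propensities rather than hourly density ratios, and they
must be **unstabilized** so each adherence class carries its
strategy-consistent mass: a subject dying inside grace could not have
deviated from either strategy (weight 1 in the early arm); a treated
survivor is weighted by the inverse probability of initiating within grace
given the covariate path, 1 − Π(1 − p̂) integrated over the alive
person-hour grid; a never-adherent clone by the inverse probability of its
observed untreated hours. (A numerator-stabilized version re-weights
grace-period deaths against treated survivors by roughly 1/P(initiate within
grace) and visibly biased the null risk difference; the estimator
Hajek-normalises, so only within-arm proportionality matters.)

*Ridge stabilization.* Both nuisance models are logistic regressions with a
weakly-informative ridge on standardized coefficients (penalty 2.0 on an
absolute scale, equivalent to a N(0, 0.5²) prior per standardized log-odds
coefficient; intercept, time spline and the arm indicator are never
penalised). The penalty is fixed in absolute terms, so its influence
vanishes as person-time grows; at small cohort sizes it prevents the
events-per-variable regime from destabilising the weights.

*Diagnostics.* Standardized mean differences use the weighted mean
difference over the unweighted pooled SD, computed among adherent clones at
time zero, before (unit weights) and after (adherence-propensity) weighting,
against the |SMD| < 0.1 convention. Variance inflation factors come from
regressing each weight-model covariate on the rest.

## Outcome models

**Weighted Cox.** The arm hazard ratio comes from a weight-incorporating
partial likelihood on counting-process episodes (lifelines, Efron ties,
entry/exit in days). Episodes are split at day boundaries inside the grace
window — the weights themselves are estimated hourly, but risk-set weighting
at day resolution in the first three days changes nothing visible while
cutting the row count two orders of magnitude — and run as one frozen-weight
episode afterwards. Covariates: the weight-model baseline set plus systolic
and mean arterial pressure, temperature, pH, bicarbonate, lactate,
hemoglobin, blood urea nitrogen and creatinine at time zero. The sandwich
variance is clustered on subject (clones duplicate individuals). A tiny
ridge (escalated 0 → 1e-3 → 1e-2 → 1e-1 only on convergence failure)
stabilises near-collinear draws. Proportional hazards are examined with
scaled Schoenfeld residuals against Kaplan–Meier-transformed time; because
residuals are not defined on left-truncated episodes, the diagnostic refits
the model on one row per clone with its frozen weight. The global statistic
sums the per-covariate chi-squares (exact for one covariate, an independence
approximation otherwise).

**Weibull AFT.** A sensitivity analysis free of the proportional-hazards
assumption: lifelines' Weibull accelerated-failure-time fit on one row per
clone with frozen weights; exp(arm coefficient) is the acceleration factor
(AF). Reporting follows the convention (1 − AF)·100 "% reduction in survival
time" for AF < 1 and "AF times longer" otherwise. Cluster-robust standard
errors are assembled in-package: per-row numerical scores at the MLE, summed
within subjects, sandwiched between lifelines' observed-information inverse.
On Weibull proportional-hazards data the two parameterizations satisfy
HR = AF^(−k) (shape k), which the tests exploit as a self-consistency check.

**AIPW.** For strategy *a* the fixed-horizon risk is the Hajek-normalised
augmented estimator

    psi_a = mean_i m_a(X_i) + sum_i D_i(a) w_i (Y_i − m_a(X_i)) / sum_i D_i(a) w_i,

with Y death by the horizon (fully observed in the synthetic setting),
D(a) adherence through the grace period (grace-window deaths adhere to both
strategies), w the adherence propensities above, and m_a a ridge-stabilised
weighted logistic regression of Y on the arm indicator and the time-zero
covariate set among adherent clones. The estimator is consistent if either
nuisance model is correct; the augmentation term vanishes in-sample by the
score equation, so with unit weights it collapses to the outcome-model
g-formula. Confidence intervals come from the empirical influence function
with two finite-sample refinements: HC3-style residual inflation
(r/(1 − leverage); the outcome model is fitted on the same rows its residual
term averages over) and a first-order term for the estimated outcome
coefficients. The risk-difference SE uses per-subject influence differences,
so the covariance from shared subjects is automatic. No cross-fitting by
default (exposed as future work, not a flag, since the in-sample corrections
proved sufficient at the sizes studied). A naive comparator,
`fit_naive_cox`, classifies subjects as ever/never treated — unadjusted by
default, i.e. the crude analysis carrying both confounding by indication and
immortal time bias; passing the covariate set isolates the immortal-time
component (≈ HR 0.89 under the null scenario, versus ≈ 1.45 crude).

## The synthetic cohort generator

Hour 0 is ICU admission. All stochastic inputs are materialised as
per-subject, per-step uniforms, so potential outcomes can be replayed on
shared randomness.

*Baseline.* Age ~ N(65, 15) clipped to [18, 95]; 40% female; race
categorical; CCI ~ round(N(7, 3)) in [0, 20]; sepsis 62%; mechanical
ventilation 40%; CKD 8% and non-full-code 8% (eligibility filters); hospital
time before ICU ~ U(0, 48) h; scheduled ICU episode ~ lognormal
(median ≈ 110 h), treatment- and death-independent, used only by the
eligibility rules.

*Severity paths.* Vitals and labs are mean-reverting AR(1) processes around
subject-specific set points with Table-1-like magnitudes (e.g. SOFA
stationary sd 1.6 with hourly autocorrelation 0.995 — a score that moves
slowly). A plain random walk was rejected: it drifts to the clipping bounds
within days and makes the covariate distributions bimodal. Creatinine is a
geometric ramp toward a subject-specific peak ratio (25% of subjects have no
AKI; the rest lognormal peaks, median ≈ 2× baseline over ~30 h) times AR(1)
noise; the renal injury also raises the SOFA set point, which is what makes
initiation confounded with prognosis. Hourly resolution covers the first
week (168 h); afterwards the processes continue with exact 24-h AR(1)
aggregation to day 90.

*Initiation.* A discrete-time logistic hazard per hour, by default
0.22·SOFA + 0.55·sepsis + 0.010·age with an acute-phase decay (e-folding
48 h) and an intercept calibrated so that roughly a fifth of eligible
subjects initiate within 72 h of eligibility — the magnitude seen in severe
AKI cohorts. Because the decay runs on ICU time, the hour of eligibility is
itself a confounder; it is therefore part of every adjustment set.

*Death.* A logistic hazard per step (hourly through the first week, daily
after, with an interval-length offset), by default 0.16·SOFA + 0.022·age +
0.18·lactate + 0.07·CCI plus an acute-phase decay (e-folding 500 h), giving
≈ 17% 90-day mortality among eligible subjects, three quarters of it within
30 days. Once RRT has begun the linear predictor shifts by the treatment
log-HR — a scalar, or a mapping from KDIGO stage to effect. The stage used
is the **peak stage reached by the initiation hour**: severity attained, not
the instantaneous value, so a transient creatinine dip cannot move a subject
between effect groups on one counterfactual arm but not the other.

*Scenarios.* `null_scenario` (log-HR 0 everywhere), `protective_scenario`
(log-HR −0.40), and `stage_split_scenario` (+0.30 below stage 3, −0.50 at
stage 3) — the last constructs the clinical dichotomy the two-trial design
is meant to detect: a positive risk difference in the broad cohort, a
negative one in the severe cohort. All default scenarios include light
missingness (2–15% on selected labs/vitals, 4% on CCI), handled by the
imputation stage.

*Ground truth.* Among the eligible subjects of a given trial, both potential
paths are replayed on shared uniforms: **early** initiates at the subject's
natural initiation hour when that falls inside the grace window and at the
close of the window otherwise (with a 1-h grace this is initiation at the
first eligible hour); **never** never initiates. This is the potential
outcome of the strategy the emulation actually enforces; defining the early
truth as "treat at time zero" instead shifts it by about one percentage
point under a log-HR of −0.4 purely through initiation timing inside the
grace window, which is an estimand difference, not estimator error. Under a
null effect the two arms are identical draws and the true risk difference is
exactly zero.

*What the generator does not emulate.* No treatment→covariate feedback (RRT
does not alter the simulated creatinine or SOFA paths), no urine-output
dynamics, no ICU readmissions, no post-discharge loss to follow-up (death is
always observed), and no fitting of the marginals to any real data set.
Passing tests therefore establish internal validity of the estimators under
confounded initiation with slowly-varying severity — not performance under
treatment-confounder feedback or informative dropout.

## Missing data

Records missing sex are dropped. Time-varying fields are filled from the
preceding hour (LOCF); a gap at the very start of a record is filled from
the subject's first observed value, since no preceding hour exists.
Incomplete baseline fields go through chained-equations imputation with
predictive mean matching (donor pool k = 5, 10 sweeps, OLS mean model, draws
restricted to the observed support); analyses use the first completed table,
with m > 1 tables available for diagnostics. Pooling across imputations is
deliberately not applied.

## Numerical choices and study sizes

Tie-breaks and degenerate inputs: events take precedence over censoring at
tied hours; an all-one/all-zero outcome vector yields a constant outcome
model; zero pooled SD yields SMD 0 when means agree, else a flagged
undefined; perfectly collinear covariates yield an infinite VIF with a named
warning; fitted probabilities of exactly 0/1 in the weight models raise
rather than propagate.

The validation studies run at sizes where each check is informative on one
CPU: null calibration with 200 cohorts of n = 1,000; effect recovery with
100 cohorts of n = 5,000 against ground truth; double robustness with 40
cohorts of n = 3,000 per misspecification arm; the crude-versus-CCW contrast
with 100 cohorts of n = 2,000 (chosen so estimator noise does not mask the
naive estimate's systematic bias); weight-balance diagnostics at n = 20,000
(the SMD of a 3%-prevalence binary covariate is Monte-Carlo noise around the
0.1 line in small cohorts). The severe-cohort emulation yields roughly 900
eligible subjects per 12,000 simulated — single-cohort severe-trial
estimates carry confidence intervals of ±5–10 percentage points, which is
why reported headline numbers average a few cohorts.

## Known limitations

The weighted survival-curve variance is not corrected for weight estimation
(curves are descriptive). The never-arm deviations after the grace window
are censored unweighted, per the frozen-weight design; with the default
initiation decay this late-deviation mass is small, but a generator with
substantial late initiation would reintroduce selection there. The global
Schoenfeld statistic is an independence approximation across covariates.
AIPW interval estimates are first-order; at a few hundred eligible subjects
they remain slightly anti-conservative in the extreme-weight tail.
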