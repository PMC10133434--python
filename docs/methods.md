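# Methods

This note documents the models, conventions and design choices behind
`sepsisaf`, and what the built-in validation studies do and do not show.

## Estimand and estimator

The target is the time-dependent attributable mortality fraction of
nosocomial sepsis: among deaths occurring by hospital day *i*, the
proportion that would not have occurred had the patients not acquired
sepsis in hospital. The estimator follows the classical case–control
route: daily odds ratios `OR_i` of death-by-day-*i* given prior sepsis
from a pooled logistic model, combined with the observed exposure
prevalence among accumulated deaths `P_c_i` through Miettinen's formula
`AF_i = P_c_i (OR_i − 1)/OR_i`. The formula is exact when `OR_i` equals
the causal risk ratio among the exposed; using the odds ratio in its place
relies on in-hospital death being reasonably rare in the source
population.

### Conventions

* Hospital days are 1-based; admission day is day 1.
* An infection surfacing on days 1–2 is community-acquired: it never
  counts as exposure, under any definition.
* Exposure must precede the day it explains: the model indicator
  `sepsis_by_t` (and likewise `event_by_t`) switches on at `t = onset + 1`.
  The cohort generator applies the true effect with the same lag, so the
  discrete-hazard fit is exactly correctly specified.
* Outcome coding: the default is *cumulative status* (`y_t` = died on or
  before *t*; every patient contributes all 28 rows, covariates frozen
  after the hospital stay ends). A *discrete hazard* coding (death at *t*
  among patients still in hospital; rows end at the outcome day) is
  available behind `hazard_coding=True` and is what the parameter-recovery
  studies use, because there the generator's log odds ratio is literally
  the model coefficient.

## Clinical phenotyping

Seven acute organ-failure criteria are screened per day (systolic BP < 90
or MAP < 65 mmHg or SBP drop > 40 mmHg; P/F < 300 or supplemental oxygen
need; altered mental status; creatinine ≥ 2 mg/dL or oliguria; bilirubin
> 2 mg/dL; platelets < 100 × 10³/mm³; INR > 1.5 or aPTT > 60 s off
anticoagulants). Missing measurements never trigger a criterion
(conservative; no imputation).

Qualifying days are graded: with antibiotics — *definitive* (positive
culture, no same-day clinically relevant event) or *very probable* (any
other culture/event combination); without antibiotics — *probable* (no
event) or *possible* (event). Because cultures are only collected under
antibiotic treatment, a recorded culture without antibiotics raises a
consistency warning and is ignored; an antibiotic day whose culture was
not collected is graded like a negative one. Recorded infection-source
information is required for the antibiotic-based tiers and the main
definition (`require_source=False` relaxes this for datasets lacking the
field); an antibiotic day without source information is left ungraded,
since the grading table has no row for it.

Consecutive qualifying days merge into episodes; a gap of `episode_gap`
(default 2) non-qualifying days starts a new episode; the episode tier is
the highest attained. "Antibiotic use" for the tier definitions means an
active antibiotic on the qualifying day; the SOFA-increase definition
instead requires a *newly started* antibiotic, mirroring the distinction
between ongoing prescription and escalation.

SOFA subscores use the standard published bandings where the collected
variables permit: vasopressor dose and ventilation are not collected, so
the cardiovascular subscore saturates at 1 (MAP < 70) and respiration is
scored from P/F bands alone; the binary mental-status flag maps to a CNS
subscore of 2. This is a documented approximation, adequate for detecting
a ≥ 2-point rise from the admission-day baseline.

## Matching and sample size

Greedy 1:1 nearest-discharge matching without replacement, in
chronological order of case death date; controls must share hospital and
admission type and fall within a 30-day margin; ties break by earlier
control admission then lower id. Greedy matching is the mechanisation of
manual nearest-discharge pairing; no optimal-assignment matching is
attempted.

The two-proportion sample size uses the normal-approximation formula with
the Fleiss–Tytun–Ury (Casagrande–Pike–Smith) continuity correction applied
to the unrounded uncorrected size; an odds ratio is converted to the case
prevalence via `p1 = OR·p0/(1 + p0(OR − 1))`. The classical worked value
(p0 = 0.2, p1 = 0.4, α = 0.05, power 0.8) gives n = 91 per group and the
Monte-Carlo attained power of the continuity-corrected test at that n is
0.80.

## Exposure weights

The acquisition model is a pooled logistic regression of first-onset
hazard on age, Charlson index and prior clinically relevant events, fitted
on at-risk person-days (days up to and including first onset; later days
excluded — a first-event formulation, since repeat episodes affect
classification but not weighting). Raw weights multiply
`1/P(observed status)` per day; stabilised weights (the default) use an
intercept-only hazard fitted on the same risk set as numerator, and
truncation clips at the 1st/99th percentile of each day's weight
distribution. A fitted probability of exactly 0 or 1 aborts with a
positivity error. On simulated cohorts of ≥ 5000 patients the per-day mean
stabilised weight stays within a few percent of 1.

## Outcome model

`WeightedMixedLogit` maximises the weighted marginal likelihood of a
logistic regression with one Gaussian random intercept per hospital.
Weights enter as frequency-type multipliers on the conditional
log-likelihood terms (the estimating-equation convention of marginal
structural models). The intercept is integrated by *adaptive*
Gauss–Hermite quadrature (default 7 nodes): each cluster's integrand is
re-centred at its posterior mode — found by a damped, vectorised scalar
Newton iteration — and re-scaled by the local curvature, which keeps the
rule accurate for the very large, sharply peaked clusters that
person-period stacking produces (one node recovers the Laplace
approximation, which agrees with 15-node quadrature to ~3 decimal places
at these cluster sizes). Optimisation is L-BFGS-B over `(β, log σ)` with
an analytic gradient (the quadrature-posterior expectation of the
complete-data score); covariance is the inverse observed information,
obtained by central differences of that gradient. Covariates are
standardised internally and estimates mapped back exactly. With the
variance fixed at 0 the fit is delegated to an ordinary weighted GLM and
agrees with an independent Newton–Raphson solver to < 1e-6.

The design is: intercept; age; Charlson; infection at admission; the
day-specific weight as a covariate (the double role the motivating
analysis used — `use_ipw_covariate=False` disables it); `sepsis_by_t` and
`event_by_t`, each with three time-interaction columns. The cubic in the
day is represented in an orthonormal basis (QR of the raw Vandermonde
matrix over days 1–28) for conditioning; contrasts are always evaluated on
the raw day scale, and the basis reproduces any raw cubic exactly. Fits
are stratified by admission type. A rank check names collinear columns;
when the baseline-infection exclusion sensitivity analysis removes all
infected patients, the then-constant infection covariate leaves the
adjustment set.

Model-based covariance is reported; person-period stacking means the 28
rows of one patient are treated as independent beyond the centre random
intercept — a known limitation shared with the motivating analysis.

## Attributable fraction and intervals

`OR_i` is the contrast `exp(c_i'β)` selecting the sepsis main effect and
its interactions at day *i*; `Var(log OR_i) = c_i'Σc_i` gives the
delta-method CI. For the AF, `AF = p_c(1 − e^{−log OR})` has derivative
`p_c/OR` in `log OR`, so `Var(AF) ≈ (p_c/OR)² Var(log OR)`; `P_c_i` is
treated as a known constant (its sampling variance is ignored — a
parametric-bootstrap check shows the delta interval matches Monte-Carlo
propagation of the coefficient uncertainty within 5% of interval width).
`P_c_i` counts deaths accumulated *by* day *i* in the denominator, not all
eventual deaths.

The period-wide "average AF" weights the daily series by the number of
deaths occurring each day (default); equal-per-day weighting and a single
pooled-contrast version are also implemented, since which of the three the
phrase "average attributable fraction obtained from the model" denotes is
genuinely open. Because the marginal log OR is linear in β, the
death-weighted mean of daily log ORs and the pooled contrast coincide for
the OR; they differ for the AF.

## Synthetic cohorts and ground truth

The generator emulates a mixed hospital population: admission mix
84.9/8.3/6.8% medical/elective/urgent, age ~ Normal(63, 18.6) clipped to
[18, 100], Poisson(2) Charlson counts, 33% infected at admission, daily
hazards for clinically relevant events (0.02), first sepsis onset
(base 0.006/day, increased by age, comorbidity and prior events), death
(base 0.004/day, increased by age, comorbidity, baseline infection, a
centre-level Normal(0, 0.3²) intercept, and — from the day after a
nosocomial onset — the true sepsis effect, default log OR 1.0, optionally
a cubic polynomial in the day), and discharge (0.09/day, reduced 70%
while an episode is active). These defaults give ~7–8% hospital
mortality, a median stay near a week, and a nosocomial sepsis prevalence
of a few percent in survivors and ~3-fold that in non-survivors —
a plausible middle-income-country hospital operating point. Measurements
on septic days trigger 1–7 organ-failure criteria, with antibiotics,
culture positivity and source recording drawn per episode (0.9/0.4/0.95);
2% of ordinary days show one spurious dysfunction, and half of the
baseline-infected patients show dysfunction on days 1–2, exercising the
community-acquired exclusion.

Counterfactuals use common random numbers: the identical per-patient-day
uniforms are replayed with the sepsis effect nulled, so
`AF_true(i) = 1 − (counterfactual deaths by i)/(factual deaths by i)` is a
low-variance, model-free benchmark. Exact enumeration of a covariate-free
five-day process confirms the simulated AF against a closed-form oracle.

What the generator does **not** emulate: pathogen identities and infection
sources beyond a flag, ICU resource use, measurement error or missingness
in vitals/labs, inter-day correlation of measurements, seasonal admission
patterns, and multiple distinct nosocomial episodes per patient (repeat
qualifying runs arise only via baseline infection or spurious
dysfunction). Passing validation therefore shows the *estimation chain* is
correct under a data-generating process that matches the model's
assumptions; it does not certify performance under real-data violations of
them.

## Validation studies (`sepsisaf.validation`)

* **Parameter recovery** — 20 centres × 200 patients, all-medical,
  constant true log OR = log 2, centre SD 0.5, deterministic
  antibiotic/source recording (classified exposure ≡ true exposure).
  The discrete-hazard mixed fit recovers the log OR within 3 SE and the
  centre SD within [0.5×, 1.5×].
* **End-to-end AF recovery** — the full default pipeline (classify →
  match → IPW → weighted mixed fit → Miettinen) on 20 such cohorts; the
  day-28 AF tracks the counterfactual truth within ±0.02 on average.
  The estimator carries a systematic error of about +0.015 to +0.025 at
  this operating point, with two documented sources: the odds ratio
  exceeds the risk ratio once death-by-28 is no longer rare among the
  exposed, and the cubic time polynomial's day-28 endpoint tends to
  overshoot. Both are properties of the published estimator, not of this
  implementation (a single-day matched logistic at day 28 shows −0.01,
  and the risk-ratio identity reproduces the truth exactly).
* **Coverage** — 200 scaled-down replicates (6 centres × 150 patients,
  base hazards raised to 0.008/0.012 to keep event counts informative);
  the 95% delta-method CI for the day-14 OR covers the true OR in 95% ± 4%
  of replicates.
* **Weight calibration** — per-day mean stabilised weight within
  [0.97, 1.03] at 6000 patients; with an intercept-only acquisition model
  the stabilised weights are exactly 1.

Problem sizes (4000-patient recovery cohorts, 200 small-replicate
coverage runs, 10⁵-replicate power simulations) are chosen so the full
validation battery completes in a few minutes on one CPU while leaving
Monte-Carlo error well below the tolerances checked.

## Numerical and degenerate-input notes

* Probabilities are kept off 0/1 by the log-odds parameterisation; a
  zero base hazard short-circuits the corresponding event entirely.
* The inner Newton step for cluster modes is clipped to ±5 per iteration;
  the quadrature log-sum uses `logsumexp`.
* `σ` is optimised on the log scale with bounds `[1e-4, 20]`; below
  `1e-6` the likelihood switches to the plain weighted Bernoulli form.
* Ties in matching break deterministically (gap, admission date, id), so
  pipelines are byte-reproducible; a run manifest records SHA-256 digests
  of every output.
* Degenerate cells (fewer than `min_pairs` matched pairs) are skipped with
  a warning rather than fitted.

## Known limitations

* Early-day odds ratios on synthetic cohorts dip below 1 because exposure
  requires surviving to onset (immortal-time structure of the
  cumulative-status coding); with death-weighted averaging this can push
  the period-average AF toward or below zero even when the late-day AF is
  clearly positive. The day-resolved series is the more interpretable
  output, and the discrete-hazard coding avoids the artifact.
* `P_c` uncertainty is ignored in the delta intervals.
* No competing-risk treatment of discharge; hospital mortality is the
  outcome and survivors keep their status through day 28.
* The SOFA mapping is an approximation bounded by the collected variables.
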