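# sepsisaf — attributable mortality of nosocomial sepsis

`sepsisaf` estimates the **time-dependent attributable mortality fraction
(AF) of hospital-acquired (nosocomial) sepsis** from matched case–control
hospital data, and ships a synthetic cohort generator with counterfactual
ground truth so the whole estimation chain can be validated end to end.

It is aimed at epidemiologists and biostatisticians studying the burden of
hospital-acquired infection: the question it answers is *"what share of
in-hospital deaths by day i would not have occurred had patients not
acquired sepsis in hospital?"*.

## The method

1. **Phenotyping.** Each hospital day is screened for acute organ failure
   (hypotension, respiratory failure, altered mental status, renal and
   hepatic dysfunction, thrombocytopenia, coagulopathy without
   anticoagulants). Qualifying days are graded by antibiotic use, culture
   results and co-occurring clinically relevant events (stroke, myocardial
   infarction, falls, seizures, bleeding, ...) into tiers
   *definitive > very probable > probable > possible*; consecutive days
   merge into episodes. Sepsis is *nosocomial* only when onset is on
   hospital day ≥ 3. Four exposure definitions are supported (`main`,
   `alt1`, `alt2`, and a Sepsis-3-style `sofa` definition based on a ≥ 2
   point SOFA rise plus a new antibiotic).
2. **Design.** Each in-hospital death (case) is matched to the temporally
   closest live discharge of the same admission type at the same hospital,
   within ± 30 days. A Fleiss–Tytun–Ury two-proportion sample-size
   calculator is included.
3. **Exposure weights.** A pooled logistic model of the daily hazard of
   first sepsis onset (age, Charlson comorbidity index, prior clinically
   relevant events) yields cumulative stabilised inverse-probability
   weights `SW_t = Π q_s / Π P(A_s = a_s | history)`, truncated at the
   1st/99th day-specific percentiles.
4. **Outcome model.** A person-period (one row per patient per day)
   logistic regression with outcome `y_t` = death by day *t*, a Gaussian
   hospital random intercept, IPW weighting, and time-varying indicators
   for sepsis and events, each interacted with a cubic polynomial in the
   day. The random intercept is integrated by adaptive Gauss–Hermite
   quadrature.
5. **Attributable fraction.** With `OR_i = exp(c_i'β)` the day-*i* odds
   ratio of death given prior sepsis and `P_c_i` the share of accumulated
   deaths preceded by sepsis, Miettinen's formula gives

   ```
   AF_i = P_c_i · (OR_i − 1) / OR_i
   ```

   with delta-method 95% confidence intervals for both `OR_i` and `AF_i`,
   plus death-weighted period averages.

The generator draws counterfactual trajectories with **common random
numbers** (same uniforms, sepsis→death effect nulled), so the true AF
`1 − (counterfactual deaths)/(factual deaths)` is available exactly for
every synthetic cohort.

## Worked example

```python
from sepsisaf import SimulationConfig, simulate_cohort, true_attributable_fraction
from sepsisaf.pipeline import AnalysisOptions, analyze_cohort

cfg = SimulationConfig(n_hospitals=10, patients_per_hospital=300, seed=42)
cohort = simulate_cohort(cfg)
summary, results, _ = analyze_cohort(cohort, AnalysisOptions())
res = results[("main", "medical")]
print(res.daily_effects().loc[[6, 13, 20, 27]])
print("true AF day 28:", true_attributable_fraction(cohort, 28, "medical"))
```

prints (abridged):

```
 day    or  or_ci_low  or_ci_high   p_c     af  af_ci_low  af_ci_high
   7 0.479      0.284       0.809 0.050 -0.054     -0.109       0.000
  14 1.435      1.087       1.893 0.101  0.031      0.011       0.050
  21 2.222      1.718       2.874 0.122  0.067      0.053       0.081
  28 6.068      3.565      10.328 0.163  0.136      0.122       0.150

true AF day 28: 0.1067
```

Reading the output: by day 28, 16.3% of the accumulated deaths were
preceded by nosocomial sepsis (`p_c`), the adjusted odds of dying by day 28
were 6.1-fold higher given prior sepsis, and an estimated 13.6% (95% CI
12.2–15.0%) of deaths by day 28 are attributable to nosocomial sepsis —
against a counterfactual truth of 10.7% for this cohort. The AF rises with
time, as longer stays accumulate exposure; early-day odds ratios below 1
reflect the survival required to acquire sepsis at all (see
`docs/methods.md`).

A command-line interface mirrors the stages:

```bash
sepsis-af simulate --seed 1 --out run/
sepsis-af run-all --seed 1 --definition main --definition alt1 --out run/
sepsis-af samplesize --p0 0.2 --p1 0.4 --power 0.8   # -> n per group: 91
```

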