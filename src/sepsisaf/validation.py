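"""Built-in validation studies: parameter recovery, interval coverage and
weight calibration on synthetic cohorts with known ground truth.

These functions define the package's standard simulation experiments; the
test suite and the reproduction script both call them rather than
re-implementing the designs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .afmodel import (
    AttributableFractionModel,
    build_person_period,
    daily_odds_ratio,
)
from .config import SimulationConfig, SepsisHazard, DeathHazard
from .definitions import apply_definition, classify_cohort
from .pipeline import AnalysisOptions, analyze_cohort
from .simulate import simulate_cohort, true_attributable_fraction
from .weights import build_risk_set, compute_ipw, fit_acquisition_model

#: constant sepsis->death log odds ratio used by the recovery studies
RECOVERY_LOG_OR = float(np.log(2.0))
#: centre-level intercept SD used by the recovery studies
RECOVERY_CENTER_SD = 0.5


def recovery_config(seed: int, n_hospitals: int = 20, patients_per_hospital: int = 200):
    """All-medical cohort with a known constant effect and deterministic
    antibiotic/source recording, so the classified exposure coincides with
    the generated one."""
    return SimulationConfig(
        n_hospitals=n_hospitals,
        patients_per_hospital=patients_per_hospital,
        seed=int(seed),
        admission_mix=(1.0, 0.0, 0.0),
        center_sd=RECOVERY_CENTER_SD,
        sepsis_mortality_log_or=RECOVERY_LOG_OR,
        antibiotic_given_sepsis_prob=1.0,
        source_recorded_prob=1.0,
    )


def coverage_config(seed: int, n_hospitals: int = 6, patients_per_hospital: int = 150):
    """Scaled-down replicate design for interval-coverage studies: higher
    base hazards keep the event counts informative at small n."""
    return SimulationConfig(
        n_hospitals=n_hospitals,
        patients_per_hospital=patients_per_hospital,
        seed=int(seed),
        center_sd=0.3,
        sepsis_mortality_log_or=RECOVERY_LOG_OR,
        antibiotic_given_sepsis_prob=1.0,
        source_recorded_prob=1.0,
        baseline_death_hazard=DeathHazard(base=0.008),
        daily_sepsis_hazard=SepsisHazard(base=0.012),
    )


def _unit_weights(patients, horizon=28):
    return pd.DataFrame(
        {
            "patient_id": np.repeat(patients["patient_id"].to_numpy(), horizon),
            "day": np.tile(np.arange(1, horizon + 1), len(patients)),
            "truncated_weight": 1.0,
        }
    )


def _hazard_fit(cohort):
    """Discrete-hazard mixed fit with true-model covariates, unit weights."""
    eps = classify_cohort(cohort.patient_days)
    expo = apply_definition(eps, "main")
    pp = build_person_period(
        cohort.patients,
        expo,
        _unit_weights(cohort.patients),
        cohort.patient_days,
        horizon=28,
        hazard_coding=True,
    )
    model = AttributableFractionModel(
        pp, hazard_coding=True, use_ipw_covariate=False
    )
    return model.fit()


def hazard_recovery_study(seed: int = 7) -> dict:
    """Recover the constant per-day sepsis log OR and the centre SD.

    Under discrete-hazard coding the generator's effect is the model's own
    parameter, so the day-14 contrast targets exp(RECOVERY_LOG_OR) exactly
    and the centre SD targets RECOVERY_CENTER_SD.
    """
    cohort = simulate_cohort(recovery_config(seed))
    res = _hazard_fit(cohort)
    or14, ci, var = daily_odds_ratio(res._contrast, 14)
    return {
        "log_or_hat": float(np.log(or14)),
        "log_or_true": RECOVERY_LOG_OR,
        "se": float(np.sqrt(var)),
        "z_error": float((np.log(or14) - RECOVERY_LOG_OR) / np.sqrt(var)),
        "sigma_hat": res.model_fit.group_sd,
        "sigma_true": RECOVERY_CENTER_SD,
    }


def af_recovery_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """End-to-end pipeline AF at day 28 against counterfactual truth.

    Runs the full default pipeline (classify, match, IPW, weighted mixed
    fit, Miettinen) on ``n_seeds`` independent recovery cohorts and
    averages estimate and truth.
    """
    opts = AnalysisOptions()
    est, tru = [], []
    for k in range(n_seeds):
        cohort = simulate_cohort(recovery_config(base_seed + k))
        _, results, _ = analyze_cohort(cohort, opts)
        res = results[("main", "medical")]
        est.append(float(res.daily_effects().iloc[-1]["af"]))
        tru.append(true_attributable_fraction(cohort, 28, "medical"))
    return {
        "mean_estimate": float(np.mean(est)),
        "mean_truth": float(np.mean(tru)),
        "error": float(np.mean(est) - np.mean(tru)),
        "per_seed_estimates": est,
        "per_seed_truths": tru,
    }


def coverage_study(n_reps: int = 200, base_seed: int = 0) -> dict:
    """Empirical coverage of the 95% delta-method CI for the day-14 OR.

    Each replicate simulates a scaled-down cohort, fits the discrete-hazard
    mixed model and checks whether the CI covers the true constant OR.
    """
    hits = 0
    for k in range(n_reps):
        cohort = simulate_cohort(coverage_config(base_seed + k))
        res = _hazard_fit(cohort)
        _, (lo, hi), _ = daily_odds_ratio(res._contrast, 14)
        hits += lo <= np.exp(RECOVERY_LOG_OR) <= hi
    return {"coverage": hits / n_reps, "hits": hits, "n_reps": n_reps}


def ipw_calibration_study(seed: int = 11, n_hospitals: int = 10,
                          patients_per_hospital: int = 600) -> dict:
    """Per-day mean of the stabilised weights on a default cohort."""
    cfg = SimulationConfig(
        n_hospitals=n_hospitals, patients_per_hospital=patients_per_hospital,
        seed=int(seed),
    )
    cohort = simulate_cohort(cfg)
    eps = classify_cohort(cohort.patient_days)
    expo = apply_definition(eps, "main")
    risk = build_risk_set(cohort.patients, cohort.patient_days, expo)
    model = fit_acquisition_model(risk)
    w = compute_ipw(risk, model)
    means = w.groupby("day")["stabilized_weight"].mean()
    return {
        "n_patients": len(cohort.patients),
        "min_day_mean": float(means.min()),
        "max_day_mean": float(means.max()),
        "max_abs_dev": float((means - 1.0).abs().max()),
    }
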