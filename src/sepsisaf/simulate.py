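"""Synthetic hospital cohort generator with counterfactual ground truth.

Each patient carries baseline covariates (age, Charlson-like comorbidity
count, admission type and diagnosis category, infection at admission) and a
daily trajectory over a 28-day horizon: clinically relevant events, first
nosocomial sepsis onset, in-hospital death and live discharge are drawn as
competing daily Bernoulli events on the log-odds scale, with a Gaussian
centre-level random intercept on the death hazard.

Counterfactual trajectories are generated with common random numbers: the
identical uniform streams are replayed with the sepsis->death effect set to
zero, so the true attributable fraction (the share of factual deaths that
would not have occurred without nosocomial sepsis) is computable exactly up
to Monte-Carlo error, without any modelling step.

Conventions
-----------
* Hospital days are 1-based; admission day is day 1.
* The sepsis->death effect applies from the day *after* onset (exposure must
  precede the day it explains) and only for hospital-acquired onsets
  (onset day >= 3); an infection surfacing on days 1-2 is treated as
  community-acquired and carries no simulated excess hazard.
* Death is evaluated before discharge within a day; patients still in
  hospital at the horizon are recorded as discharged alive on the last day.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (
    ADMISSION_CATEGORIES,
    ADMISSION_TYPES,
    NOSOCOMIAL_MIN_ONSET_DAY,
    SimulationConfig,
)

PATIENT_COLUMNS = [
    "patient_id",
    "hospital_id",
    "admission_type",
    "admission_category",
    "age",
    "charlson",
    "infection_at_admission",
    "admission_date",
    "outcome",
    "outcome_day",
    "is_case",
    "sepsis_onset_day_true",
]

OBSERVATION_COLUMNS = [
    "patient_id",
    "day",
    "systolic_bp",
    "mean_ap",
    "sbp_drop",
    "pf_ratio",
    "on_supplemental_o2_for_spo2",
    "mental_status_abnormal",
    "creatinine",
    "low_urine_output_2h",
    "bilirubin",
    "platelets",
    "inr",
    "aptt",
    "on_anticoagulant",
    "new_antibiotic_started",
    "antibiotic_active",
    "culture_result",
    "suspected_source_recorded",
    "clinically_relevant_event",
    "locale",
]


@dataclass
class Cohort:
    """Container for one simulated population.

    Attributes
    ----------
    patients : one row per patient (baseline covariates and outcome).
    patient_days : long table, one row per in-hospital patient-day.
    truth : per-patient factual and counterfactual death days.
    """

    patients: pd.DataFrame
    patient_days: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": out / "patients.csv",
            "patient_days": out / "patient_days.csv",
            "truth": out / "truth.csv",
        }
        self.patients.to_csv(paths["patients"], index=False)
        self.patient_days.to_csv(paths["patient_days"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _trajectories(cfg, base, draws, effect_on):
    """Replay the daily competing-event process from shared uniforms.

    Returns onset day, death day, discharge day (0 = never) and the
    event-occurrence matrix, for either the factual arm (``effect_on=True``)
    or the no-sepsis-effect counterfactual.
    """
    n = base["age"].shape[0]
    T = cfg.horizon_days
    sh = cfg.daily_sepsis_hazard
    dh = cfg.baseline_death_hazard

    sep_lp0 = (
        logit(max(sh.base, 1e-12))
        + sh.age * (base["age"] - cfg.age_mean)
        + sh.charlson * base["charlson"]
    )
    death_lp0 = (
        logit(max(dh.base, 1e-12))
        + base["b_center"]
        + dh.age * (base["age"] - cfg.age_mean)
        + dh.charlson * base["charlson"]
        + dh.infection * base["infection"]
    )

    active = np.ones(n, dtype=bool)
    onset = np.zeros(n, dtype=np.int64)
    death = np.zeros(n, dtype=np.int64)
    discharge = np.zeros(n, dtype=np.int64)
    prior_event = np.zeros(n, dtype=bool)
    events = np.zeros((n, T), dtype=bool)

    for t in range(1, T + 1):
        j = t - 1
        ev = active & (draws["event"][:, j] < cfg.daily_event_hazard)
        events[:, j] = ev

        # first sepsis onset: only on event-free in-hospital days, so the
        # generated onset day satisfies the main clinical definition
        eligible = active & (onset == 0) & ~ev
        if cfg.daily_sepsis_hazard.base > 0:
            p_sep = expit(sep_lp0 + sh.event * prior_event)
            new_onset = eligible & (draws["sepsis"][:, j] < p_sep)
            onset[new_onset] = t

        exposed = (
            (onset > 0)
            & (onset >= NOSOCOMIAL_MIN_ONSET_DAY)
            & (onset <= t - 1)
        )
        lp = death_lp0.copy()
        if effect_on:
            lp += cfg.sepsis_effect_at(t) * exposed
        if dh.base > 0:
            die = active & (draws["death"][:, j] < expit(lp))
        else:
            die = np.zeros(n, dtype=bool)
        death[die] = t

        sep_active = (onset > 0) & (t >= onset) & (
            t < onset + cfg.sepsis_duration_days
        )
        p_disc = np.where(
            sep_active,
            cfg.discharge_hazard * cfg.discharge_hazard_ratio_sepsis,
            cfg.discharge_hazard,
        )
        disc = active & ~die & (draws["discharge"][:, j] < p_disc)
        discharge[disc] = t

        active &= ~(die | disc)
        prior_event |= ev

    discharge[active] = T  # administrative end of follow-up, alive
    return onset, death, discharge, events


def _normal_measurements(rng, m):
    """Baseline (non-dysfunctional) daily measurements for ``m`` rows."""
    return {
        "systolic_bp": np.clip(rng.normal(125.0, 10.0, m), 100.0, None).round(1),
        "mean_ap": np.clip(rng.normal(85.0, 8.0, m), 70.0, None).round(1),
        "sbp_drop": np.clip(rng.normal(5.0, 5.0, m), 0.0, 30.0).round(1),
        "pf_ratio": np.clip(rng.normal(380.0, 40.0, m), 320.0, None).round(0),
        "on_supplemental_o2_for_spo2": np.zeros(m, dtype=bool),
        "mental_status_abnormal": np.zeros(m, dtype=bool),
        "creatinine": np.clip(rng.normal(1.0, 0.2, m), 0.4, 1.8).round(2),
        "low_urine_output_2h": np.zeros(m, dtype=bool),
        "bilirubin": np.clip(rng.normal(0.8, 0.3, m), 0.1, 1.8).round(2),
        "platelets": np.clip(rng.normal(250e3, 50e3, m), 120e3, None).round(0),
        "inr": np.clip(rng.normal(1.0, 0.1, m), 0.8, 1.4).round(2),
        "aptt": np.clip(rng.normal(30.0, 5.0, m), 20.0, 50.0).round(1),
    }


_DYSFUNCTION_SYSTEMS = (
    "cardiovascular",
    "respiratory",
    "neurologic",
    "renal",
    "hepatic",
    "hematologic",
    "coagulation",
)


def _inject_dysfunction(rng, obs, rows, systems):
    """Overwrite measurements so the given rows trigger organ-failure criteria.

    ``systems`` is a boolean (len(rows) x 7) matrix in `_DYSFUNCTION_SYSTEMS`
    order.
    """
    idx = rows[systems[:, 0]]
    obs["systolic_bp"][idx] = rng.uniform(70.0, 88.0, idx.size).round(1)
    obs["mean_ap"][idx] = rng.uniform(48.0, 64.0, idx.size).round(1)
    idx = rows[systems[:, 1]]
    obs["pf_ratio"][idx] = rng.uniform(150.0, 295.0, idx.size).round(0)
    idx = rows[systems[:, 2]]
    obs["mental_status_abnormal"][idx] = True
    idx = rows[systems[:, 3]]
    obs["creatinine"][idx] = rng.uniform(2.2, 4.0, idx.size).round(2)
    idx = rows[systems[:, 4]]
    obs["bilirubin"][idx] = rng.uniform(2.5, 6.0, idx.size).round(2)
    idx = rows[systems[:, 5]]
    obs["platelets"][idx] = rng.uniform(30e3, 90e3, idx.size).round(0)
    idx = rows[systems[:, 6]]
    obs["inr"][idx] = rng.uniform(1.6, 2.5, idx.size).round(2)
    obs["on_anticoagulant"][idx] = False


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Generate a synthetic population with counterfactual ground truth.

    Parameters
    ----------
    config : SimulationConfig
        Data-generating parameters; validated before use.
    seed : int, optional
        Overrides ``config.seed``.

    Returns
    -------
    Cohort with ``patients``, ``patient_days`` and ``truth`` tables.  The
    tables are byte-reproducible given the same configuration and seed.
    """
    cfg = config.validate()
    root = np.random.SeedSequence(cfg.seed if seed is None else int(seed))
    ss_base, ss_traj, ss_meas, ss_episode = root.spawn(4)
    rng = np.random.default_rng(ss_base)
    n = cfg.n_hospitals * cfg.patients_per_hospital
    T = cfg.horizon_days

    hospital = np.repeat(np.arange(1, cfg.n_hospitals + 1), cfg.patients_per_hospital)
    b_center_by_hosp = rng.normal(0.0, cfg.center_sd, cfg.n_hospitals)
    admission_type_idx = rng.choice(3, size=n, p=np.asarray(cfg.admission_mix))
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18.0, 100.0).round(1)
    charlson = rng.poisson(cfg.charlson_rate, n)
    infection = rng.random(n) < cfg.baseline_infection_prob
    admission_date = rng.integers(0, 366, n)
    # diagnosis category; baseline infection pushes toward the infection label
    cat_idx = rng.integers(0, len(ADMISSION_CATEGORIES), n)
    cat_idx = np.where(
        infection & (rng.random(n) < 0.7),
        ADMISSION_CATEGORIES.index("infection"),
        cat_idx,
    )

    base = {
        "age": age,
        "charlson": charlson.astype(float),
        "infection": infection.astype(float),
        "b_center": b_center_by_hosp[hospital - 1],
    }
    rng_traj = np.random.default_rng(ss_traj)
    draws = {
        name: rng_traj.random((n, T))
        for name in ("event", "sepsis", "death", "discharge")
    }

    onset, death, discharge, events = _trajectories(cfg, base, draws, effect_on=True)
    _, death_cf, _, _ = _trajectories(cfg, base, draws, effect_on=False)

    outcome_day = np.where(death > 0, death, discharge)
    is_case = death > 0

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "hospital_id": hospital,
            "admission_type": np.asarray(ADMISSION_TYPES)[admission_type_idx],
            "admission_category": np.asarray(ADMISSION_CATEGORIES)[cat_idx],
            "age": age,
            "charlson": charlson,
            "infection_at_admission": infection,
            "admission_date": admission_date,
            "outcome": np.where(is_case, "died", "discharged_alive"),
            "outcome_day": outcome_day,
            "is_case": is_case,
            "sepsis_onset_day_true": onset,
        }
    )

    truth = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "factual_death_day": np.where(death > 0, death, np.nan),
            "counterfactual_death_day_no_sepsis_effect": np.where(
                death_cf > 0, death_cf, np.nan
            ),
            "shared_seed": cfg.seed if seed is None else int(seed),
        }
    )

    patient_days = _build_observations(
        cfg, patients, onset, events, ss_meas, ss_episode
    )
    return Cohort(patients=patients, patient_days=patient_days, truth=truth, config=cfg)


def _build_observations(cfg, patients, onset, events, ss_meas, ss_episode):
    rng = np.random.default_rng(ss_meas)
    rng_ep = np.random.default_rng(ss_episode)
    n = len(patients)
    T = cfg.horizon_days
    outcome_day = patients["outcome_day"].to_numpy()
    infection = patients["infection_at_admission"].to_numpy()

    pid = np.repeat(patients["patient_id"].to_numpy(), outcome_day)
    day = np.concatenate([np.arange(1, d + 1) for d in outcome_day]) if n else np.array([], int)
    m = pid.size
    row_patient = np.repeat(np.arange(n), outcome_day)

    obs = _normal_measurements(rng, m)
    obs["on_anticoagulant"] = rng.random(m) < 0.10
    obs["new_antibiotic_started"] = np.zeros(m, dtype=bool)
    obs["antibiotic_active"] = np.zeros(m, dtype=bool)
    culture = np.full(m, "not_collected", dtype=object)
    obs["suspected_source_recorded"] = np.zeros(m, dtype=bool)
    obs["clinically_relevant_event"] = events[row_patient, day - 1]

    # --- episode-level draws for the generated sepsis episode ------------
    has_sepsis = onset > 0
    abx_drawn = rng_ep.random(n) < cfg.antibiotic_given_sepsis_prob
    culture_pos = rng_ep.random(n) < cfg.culture_positive_prob
    source_drawn = rng_ep.random(n) < cfg.source_recorded_prob
    n_sys = len(_DYSFUNCTION_SYSTEMS)
    sys_draw = rng_ep.random((n, n_sys)) < 0.35
    none_drawn = ~sys_draw.any(axis=1)
    forced = rng_ep.integers(0, n_sys, n)
    sys_draw[np.arange(n)[none_drawn], forced[none_drawn]] = True

    sepsis_day = (
        has_sepsis[row_patient]
        & (day >= onset[row_patient])
        & (day < onset[row_patient] + cfg.sepsis_duration_days)
    )
    sep_rows = np.flatnonzero(sepsis_day)
    if sep_rows.size:
        _inject_dysfunction(rng, obs, sep_rows, sys_draw[row_patient[sep_rows]])
        abx_rows = sep_rows[abx_drawn[row_patient[sep_rows]]]
        obs["antibiotic_active"][abx_rows] = True
        onset_rows = abx_rows[day[abx_rows] == onset[row_patient[abx_rows]]]
        obs["new_antibiotic_started"][onset_rows] = True
        culture[onset_rows] = np.where(
            culture_pos[row_patient[onset_rows]], "positive", "negative"
        )
        src_rows = sep_rows[source_drawn[row_patient[sep_rows]]]
        obs["suspected_source_recorded"][src_rows] = True
        # no clinically relevant event on the onset day by construction;
        # keep the whole qualifying run event-free so the episode is clean
        obs["clinically_relevant_event"][sep_rows] = False

    # --- community-acquired infection at admission ------------------------
    base_abx = infection[row_patient] & (day <= 3)
    obs["antibiotic_active"][base_abx] = True
    obs["new_antibiotic_started"][base_abx & (day == 1)] = True
    base_dysf_pat = infection & (rng_ep.random(n) < 0.5)
    base_rows = np.flatnonzero(base_dysf_pat[row_patient] & (day <= 2) & ~sepsis_day)
    if base_rows.size:
        one_sys = np.zeros((base_rows.size, n_sys), dtype=bool)
        one_sys[np.arange(base_rows.size), rng.integers(0, n_sys, base_rows.size)] = True
        _inject_dysfunction(rng, obs, base_rows, one_sys)
        cult1 = base_rows[day[base_rows] == 1]
        culture[cult1] = np.where(
            rng.random(cult1.size) < cfg.culture_positive_prob, "positive", "negative"
        )
        obs["suspected_source_recorded"][
            base_rows[rng.random(base_rows.size) < cfg.source_recorded_prob]
        ] = True

    # --- sporadic non-septic organ dysfunction ----------------------------
    spur = np.flatnonzero(
        (rng.random(m) < cfg.spurious_dysfunction_prob) & ~sepsis_day & ~base_abx
    )
    if spur.size:
        one_sys = np.zeros((spur.size, n_sys), dtype=bool)
        one_sys[np.arange(spur.size), rng.integers(0, n_sys, spur.size)] = True
        _inject_dysfunction(rng, obs, spur, one_sys)

    locale = np.where(
        sepsis_day & (rng.random(m) < 0.45),
        "icu",
        np.where(rng.random(m) < 0.12, "icu", "ward"),
    )

    frame = pd.DataFrame({"patient_id": pid, "day": day})
    for key in OBSERVATION_COLUMNS[2:]:
        if key == "culture_result":
            frame[key] = culture
        elif key == "locale":
            frame[key] = locale
        else:
            frame[key] = obs[key]
    return frame


def true_attributable_fraction(
    cohort: Cohort, day: int, admission_type: str | None = None
) -> float:
    """Simulation-true attributable fraction of deaths by ``day``.

    Computed directly from the shared-randomness counterfactual:
    ``1 - (counterfactual deaths by day) / (factual deaths by day)``,
    optionally restricted to one admission type.  Returns 0.0 when there
    are no factual deaths by ``day``.
    """
    if not (1 <= int(day) <= cohort.config.horizon_days):
        raise ValueError(
            f"day must be in 1..{cohort.config.horizon_days}, got {day}"
        )
    truth = cohort.truth
    if admission_type is not None:
        if admission_type not in ADMISSION_TYPES:
            raise ValueError(f"unknown admission type {admission_type!r}")
        keep = cohort.patients["admission_type"].to_numpy() == admission_type
        truth = truth[keep]
    factual = (truth["factual_death_day"] <= day).sum()
    counterfactual = (truth["counterfactual_death_day_no_sepsis_effect"] <= day).sum()
    if factual == 0:
        return 0.0
    return 1.0 - counterfactual / factual
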