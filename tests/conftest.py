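import numpy as np
import pandas as pd
import pytest

from sepsisaf.config import SimulationConfig
from sepsisaf.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-hospital, 2000-patient cohort shared across read-only tests."""
    cfg = SimulationConfig(n_hospitals=5, patients_per_hospital=400, seed=1)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """All-medical cohort with deterministic antibiotic/source recording,
    constant twofold sepsis->death odds and centre SD 0.5 (the parameter
    recovery operating point)."""
    from sepsisaf.validation import recovery_config

    return simulate_cohort(recovery_config(7))


def make_obs(**overrides):
    """One observation row with all measurements in the normal range."""
    row = {
        "patient_id": 1,
        "day": 5,
        "systolic_bp": 120.0,
        "mean_ap": 85.0,
        "sbp_drop": 5.0,
        "pf_ratio": 400.0,
        "on_supplemental_o2_for_spo2": False,
        "mental_status_abnormal": False,
        "creatinine": 1.0,
        "low_urine_output_2h": False,
        "bilirubin": 0.8,
        "platelets": 250_000.0,
        "inr": 1.0,
        "aptt": 30.0,
        "on_anticoagulant": False,
        "new_antibiotic_started": False,
        "antibiotic_active": False,
        "culture_result": "not_collected",
        "suspected_source_recorded": False,
        "clinically_relevant_event": False,
        "locale": "ward",
    }
    row.update(overrides)
    return row


def obs_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def normal_obs():
    return obs_frame([make_obs()])
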