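"""Reference tallies from the motivating multicentre case-control study.

These are the printed exposure counts and marginal estimates of the
Brazilian 37-hospital nosocomial-sepsis case-control study this package's
analysis design follows (1794 matched case-control pairs, 3588 patients).
They are inputs for arithmetic consistency checks -- the patient-level data
behind them are not public, so the package never tries to reproduce them
from data, only to verify that its estimation formulas are consistent with
the printed numbers.
"""

from __future__ import annotations

import numpy as np

from .afmodel import miettinen_af

N_PAIRS = 1794
N_PATIENTS = 2 * N_PAIRS

#: exposed-patient and episode tallies by definition (cases = non-survivors)
EXPOSURE_TALLIES = {
    "main": {
        "patients": 388,
        "patients_cases": 311,
        "patients_controls": 77,
        "episodes": 470,
        "episodes_cases": 387,
        "episodes_controls": 83,
    },
    "alt1": {
        "patients": 1129,
        "episodes": 1387,
        "episodes_cases": 1058,
        "episodes_controls": 329,
        "tier_patients": {"definitive": 74, "very_probable": 850, "probable": 205},
    },
    "alt2": {
        "patients": 924,
        "episodes": 1121,
        "episodes_cases": 945,
        "episodes_controls": 176,
    },
    "sofa": {
        "patients": 729,
        "episodes": 869,
        "episodes_cases": 782,
        "episodes_controls": 87,
    },
}

#: printed case/control percentages for the main definition (nosocomial rows)
MAIN_DEFINITION_PERCENTAGES = {"cases": 17.3, "controls": 4.3}

#: marginal odds ratio and average AF by (definition, admission type)
MARGINAL_ESTIMATES = {
    ("main", "medical"): {"or": 1.73, "af": 0.076, "af_ci": (0.068, 0.084)},
    ("main", "elective_surgery"): {"or": 2.75, "af": 0.043, "af_ci": (0.032, 0.055)},
    ("main", "urgent_surgery"): {"or": 1.75, "af": 0.036, "af_ci": (0.017, 0.055)},
    ("alt1", "medical"): {"or": 1.32, "af": 0.101, "af_ci": (0.083, 0.118)},
    ("alt1", "elective_surgery"): {"or": 2.85, "af": 0.374, "af_ci": (0.337, 0.412)},
    ("alt1", "urgent_surgery"): {"or": 2.21, "af": 0.230, "af_ci": (0.192, 0.268)},
    ("alt2", "medical"): {"or": 1.60, "af": 0.141, "af_ci": (0.128, 0.155)},
    ("alt2", "elective_surgery"): {"or": 3.61, "af": 0.392, "af_ci": (0.363, 0.422)},
    ("alt2", "urgent_surgery"): {"or": 2.57, "af": 0.251, "af_ci": (0.218, 0.284)},
    ("sofa", "medical"): {"or": 2.25, "af": 0.176, "af_ci": (0.167, 0.185)},
    ("sofa", "elective_surgery"): {"or": 3.52, "af": 0.358, "af_ci": (0.330, 0.386)},
    ("sofa", "urgent_surgery"): {"or": 2.93, "af": 0.246, "af_ci": (0.219, 0.274)},
}


def implied_p_c(or_value: float, af_value: float) -> float:
    """Exposure prevalence among deaths implied by a printed (OR, AF) pair.

    Inverts Miettinen's formula: ``p_c = AF * OR / (OR - 1)``.
    """
    if or_value <= 1.0:
        raise ValueError("inversion requires OR > 1")
    return af_value * or_value / (or_value - 1.0)


def check_tally_consistency(percent_tol: float = 0.05) -> dict[str, bool]:
    """Arithmetic consistency of the printed exposure tallies.

    Checks case/control sums against totals, the tier breakdown of the
    broad definition, the printed case/control percentages of the main
    definition, the prevalence-driven nesting of exposed-patient counts
    across definitions, and that every printed (OR, AF) pair implies a
    valid exposure prevalence in [0, 1] under Miettinen's formula.
    """
    t = EXPOSURE_TALLIES
    checks = {
        "main_patient_sum": t["main"]["patients_cases"]
        + t["main"]["patients_controls"]
        == t["main"]["patients"],
        "main_episode_sum": t["main"]["episodes_cases"]
        + t["main"]["episodes_controls"]
        == t["main"]["episodes"],
        "alt1_episode_sum": t["alt1"]["episodes_cases"]
        + t["alt1"]["episodes_controls"]
        == t["alt1"]["episodes"],
        "alt1_tier_sum": sum(t["alt1"]["tier_patients"].values())
        == t["alt1"]["patients"],
        "alt2_episode_sum": t["alt2"]["episodes_cases"]
        + t["alt2"]["episodes_controls"]
        == t["alt2"]["episodes"],
        "sofa_episode_sum": t["sofa"]["episodes_cases"]
        + t["sofa"]["episodes_controls"]
        == t["sofa"]["episodes"],
        "definition_nesting": t["main"]["patients"]
        <= t["alt2"]["patients"]
        <= t["alt1"]["patients"],
        "main_case_percentage": abs(
            100.0 * t["main"]["patients_cases"] / N_PAIRS
            - MAIN_DEFINITION_PERCENTAGES["cases"]
        )
        <= percent_tol,
        "main_control_percentage": abs(
            100.0 * t["main"]["patients_controls"] / N_PAIRS
            - MAIN_DEFINITION_PERCENTAGES["controls"]
        )
        <= percent_tol,
    }
    for (definition, adm), est in MARGINAL_ESTIMATES.items():
        p_c = implied_p_c(est["or"], est["af"])
        recomputed = miettinen_af(est["or"], p_c)
        checks[f"{definition}_{adm}_af_roundtrip"] = bool(
            0.0 <= p_c <= 1.0 and np.isclose(recomputed, est["af"], atol=1e-9)
        )
    return checks
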