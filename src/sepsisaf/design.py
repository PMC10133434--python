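"""Case-control selection and two-proportion sample-size calculation.

Cases are in-hospital deaths; each is paired, greedily and without
replacement in chronological order of the case's death date, with the
temporally closest live discharge of the same admission type from the same
hospital, within a configurable margin (default 30 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # case_id, control_id, admission_type, discharge_gap_days
    unmatched_cases: list[int]


def _discharge_date(patients: pd.DataFrame) -> pd.Series:
    # calendar day on which the patient left hospital (dead or alive)
    return patients["admission_date"] + patients["outcome_day"] - 1


def select_case_control(patients: pd.DataFrame, margin_days: int = 30) -> MatchResult:
    """Greedy 1:1 nearest-discharge matching.

    Controls must share hospital and admission type with their case and be
    discharged alive within ``margin_days`` of the case's death date.  Each
    control is used at most once.  Ties on the absolute date gap are broken
    by earlier control admission date, then lower control id.
    """
    if len(patients) == 0:
        raise ValueError("population is empty")
    cases = patients[patients["is_case"]].copy()
    if len(cases) == 0:
        raise ValueError("population contains no cases (in-hospital deaths)")
    controls = patients[~patients["is_case"]].copy()
    cases["event_date"] = _discharge_date(cases)
    controls["event_date"] = _discharge_date(controls)

    pairs = []
    unmatched: list[int] = []
    pool: dict[tuple, pd.DataFrame] = {
        key: g[["patient_id", "event_date", "admission_date"]].copy()
        for key, g in controls.groupby(["hospital_id", "admission_type"], sort=False)
    }
    used: set[int] = set()

    order = cases.sort_values(["event_date", "patient_id"])
    for case in order.itertuples():
        key = (case.hospital_id, case.admission_type)
        cand = pool.get(key)
        if cand is not None and used:
            cand = cand[~cand["patient_id"].isin(used)]
        if cand is None or cand.empty:
            unmatched.append(int(case.patient_id))
            continue
        gap = (cand["event_date"] - case.event_date).abs()
        eligible = gap <= margin_days
        if not eligible.any():
            unmatched.append(int(case.patient_id))
            continue
        cand = cand[eligible].assign(_gap=gap[eligible])
        cand = cand.sort_values(["_gap", "admission_date", "patient_id"])
        best = cand.iloc[0]
        used.add(int(best["patient_id"]))
        pairs.append(
            {
                "case_id": int(case.patient_id),
                "control_id": int(best["patient_id"]),
                "admission_type": case.admission_type,
                "discharge_gap_days": int(best["_gap"]),
            }
        )
    pairs_df = pd.DataFrame(
        pairs, columns=["case_id", "control_id", "admission_type", "discharge_gap_days"]
    )
    return MatchResult(pairs=pairs_df, unmatched_cases=unmatched)


def odds_ratio_to_p1(p0: float, odds_ratio: float) -> float:
    """Exposure prevalence in cases implied by ``p0`` and an odds ratio."""
    return odds_ratio * p0 / (1.0 + p0 * (odds_ratio - 1.0))


def fleiss_sample_size(
    p0: float,
    p1: float | None = None,
    odds_ratio: float | None = None,
    alpha: float = 0.05,
    power: float = 0.80,
    continuity_correction: bool = True,
) -> int:
    """Per-group sample size for detecting a difference in two proportions.

    Uses the normal-approximation formula with the continuity correction of
    Fleiss, Tytun and Ury (equivalently Casagrande-Pike-Smith), applied to
    the unrounded uncorrected size.  Either ``p1`` or ``odds_ratio`` must be
    given; an odds ratio is converted via
    ``p1 = OR*p0 / (1 + p0*(OR - 1))``.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly between 0 and 1")
    if (p1 is None) == (odds_ratio is None):
        raise ValueError("give exactly one of p1 or odds_ratio")
    if p1 is None:
        if odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        p1 = odds_ratio_to_p1(p0, odds_ratio)
    if not (0.0 < p1 < 1.0):
        raise ValueError("p1 must lie strictly between 0 and 1")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie strictly between 0 and 1")
    delta = abs(p1 - p0)
    if delta == 0.0:
        raise ValueError("effect size is null; n unbounded")

    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    p_bar = (p0 + p1) / 2.0
    q_bar = 1.0 - p_bar
    n_prime = (
        z_a * math.sqrt(2.0 * p_bar * q_bar)
        + z_b * math.sqrt(p0 * (1 - p0) + p1 * (1 - p1))
    ) ** 2 / delta**2
    if not continuity_correction:
        return math.ceil(n_prime)
    n_corr = n_prime / 4.0 * (1.0 + math.sqrt(1.0 + 4.0 / (n_prime * delta))) ** 2
    return math.ceil(n_corr)


def simulated_power(
    n: int,
    p0: float,
    p1: float,
    alpha: float = 0.05,
    n_reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the continuity-corrected two-proportion test.

    Vectorised Yates-corrected chi-square test on ``n_reps`` simulated
    2x2 tables with ``n`` subjects per group.
    """
    rng = np.random.default_rng(seed)
    x0 = rng.binomial(n, p0, n_reps).astype(float)
    x1 = rng.binomial(n, p1, n_reps).astype(float)
    tot = x0 + x1
    # expected counts under the pooled null
    p_hat = tot / (2 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        # |O - E| is identical for all four cells; the Yates statistic
        # collapses to 2*(|x1 - n*p_hat| - 0.5)^2 / (n*p_hat*(1 - p_hat))
        num = np.abs(x1 - n * p_hat) - 0.5
        num = np.clip(num, 0.0, None) ** 2
        denom = n * p_hat * (1 - p_hat)
        chi2 = np.where(denom > 0, 2.0 * num / denom, 0.0)
    crit = norm.ppf(1.0 - alpha / 2.0) ** 2
    return float(np.mean(chi2 > crit))
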