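"""Inverse probability of (time-varying) sepsis exposure weights.

The acquisition model is a pooled logistic regression for the daily hazard
of *first* nosocomial sepsis onset, fitted on person-day rows at risk (all
in-hospital days up to and including the first exposure onset; later days
are excluded).  Cumulative weights follow the marginal-structural-model
construction: at day t the raw weight is the inverse probability of the
patient's observed exposure history through min(t, onset),

    W_t = prod_{s <= t} 1 / P(A_s = a_s | covariates_s, no onset before s),

which multiplies 1/(1 - p_s) over unexposed at-risk days and 1/p_onset on
the onset day, after which the weight is carried forward.  Stabilised
weights replace the numerator with the same product from an intercept-only
(marginal) hazard model; truncation clips the day-specific weight
distribution at configurable percentiles (default 1st/99th).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

ACQUISITION_COVARIATES = ("age", "charlson", "prior_event")


class PositivityError(RuntimeError):
    """A fitted exposure probability of exactly 0 or 1 was encountered."""


@dataclass
class AcquisitionModel:
    """Fitted (or hand-specified) daily first-onset hazard model.

    ``params`` maps design-column names (``const`` plus covariates) to
    log-odds coefficients.  ``bse`` and ``llf`` are populated when the
    model was estimated from data.
    """

    params: dict[str, float]
    bse: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    llf: float = float("nan")
    nobs: int = 0

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(k for k in self.params if k != "const")

    def predict(self, person_days: pd.DataFrame) -> np.ndarray:
        """Per-row onset probability."""
        eta = np.full(len(person_days), self.params.get("const", 0.0))
        for name in self.covariates:
            eta = eta + self.params[name] * person_days[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def build_risk_set(
    patients: pd.DataFrame,
    patient_days: pd.DataFrame,
    exposures: pd.DataFrame,
) -> pd.DataFrame:
    """Person-day rows at risk of first nosocomial sepsis onset.

    One row per patient per in-hospital day up to and including the
    exposure onset day (all in-hospital days for never-exposed patients),
    with the outcome indicator ``onset`` and covariates age, charlson and
    ``prior_event`` (any clinically relevant event on an earlier day).
    """
    onset_map = exposures.set_index("patient_id")["exposure_onset_day"]
    df = patient_days[["patient_id", "day", "clinically_relevant_event"]].copy()
    df = df.sort_values(["patient_id", "day"])
    ev = df.groupby("patient_id")["clinically_relevant_event"].cumsum()
    df["prior_event"] = (
        (ev - df["clinically_relevant_event"].astype(int)) > 0
    ).astype(int)
    df["_onset_day"] = df["patient_id"].map(onset_map)
    at_risk = df["_onset_day"].isna() | (df["day"] <= df["_onset_day"])
    df = df[at_risk].copy()
    df["onset"] = (df["day"] == df["_onset_day"]).astype(int)
    df = df.merge(
        patients[["patient_id", "age", "charlson"]], on="patient_id", how="left"
    )
    return df[["patient_id", "day", "age", "charlson", "prior_event", "onset"]]


def fit_acquisition_model(
    person_days: pd.DataFrame,
    covariates: tuple[str, ...] = ACQUISITION_COVARIATES,
) -> AcquisitionModel:
    """Maximum-likelihood logistic fit of the daily first-onset hazard.

    ``person_days`` must carry an ``onset`` indicator and the requested
    covariate columns (see :func:`build_risk_set`).
    """
    y = person_days["onset"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("no exposure onsets in the risk set; cannot fit")
    X = sm.add_constant(
        person_days[list(covariates)].astype(float), has_constant="add"
    ) if covariates else pd.DataFrame(
        {"const": np.ones(len(person_days))}, index=person_days.index
    )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    params = dict(zip(X.columns, res.params))
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 50:
        raise RuntimeError(
            "acquisition model did not converge to finite coefficients "
            "(possible complete separation); largest |coef| = "
            f"{np.abs(res.params).max():.1f}"
        )
    return AcquisitionModel(
        params=params,
        bse=dict(zip(X.columns, res.bse)),
        converged=True,
        llf=float(res.llf),
        nobs=len(person_days),
    )


def compute_ipw(
    risk_set: pd.DataFrame,
    model: AcquisitionModel,
    stabilize: bool = True,
    truncate_pct: tuple[float, float] | None = (0.01, 0.99),
) -> pd.DataFrame:
    """Cumulative inverse-probability-of-exposure weights per patient-day.

    Returns a frame with columns ``patient_id``, ``day``, ``raw_weight``,
    ``stabilized_weight`` and ``truncated_weight`` covering the at-risk
    days (downstream consumers carry the last value forward).  The
    numerator model for stabilisation is an intercept-only hazard fitted on
    the same risk set.  ``truncate_pct=None`` disables truncation; with
    ``stabilize=False`` the stabilised column simply repeats the raw one
    and truncation applies to the raw weights.
    """
    df = risk_set.sort_values(["patient_id", "day"]).copy()
    p = model.predict(df)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise PositivityError(
            "fitted exposure probabilities of 0 or 1 encountered; "
            "the positivity assumption fails on this data"
        )
    y = df["onset"].to_numpy(dtype=float)
    # P(observed exposure status this day | history)
    p_obs = np.where(y == 1, p, 1.0 - p)
    log_denom = pd.Series(np.log(p_obs), index=df.index)
    df["raw_weight"] = np.exp(-log_denom.groupby(df["patient_id"]).cumsum())

    if stabilize:
        numerator = fit_acquisition_model(df, covariates=())
        q = numerator.predict(df)
        q_obs = np.where(y == 1, q, 1.0 - q)
        log_num = pd.Series(np.log(q_obs), index=df.index)
        cum_num = np.exp(log_num.groupby(df["patient_id"]).cumsum())
        df["stabilized_weight"] = df["raw_weight"] * cum_num
    else:
        df["stabilized_weight"] = df["raw_weight"]

    target = df["stabilized_weight"]
    if truncate_pct is not None:
        lo_q, hi_q = truncate_pct
        if not (0.0 <= lo_q < hi_q <= 1.0):
            raise ValueError("truncate_pct must satisfy 0 <= lo < hi <= 1")
        bounds = target.groupby(df["day"]).quantile([lo_q, hi_q]).unstack()
        lo = df["day"].map(bounds[lo_q])
        hi = df["day"].map(bounds[hi_q])
        df["truncated_weight"] = target.clip(lower=lo, upper=hi)
    else:
        df["truncated_weight"] = target
    return df[
        ["patient_id", "day", "raw_weight", "stabilized_weight", "truncated_weight"]
    ]


def extend_weights(
    weights: pd.DataFrame,
    patients: pd.DataFrame,
    horizon: int,
) -> pd.DataFrame:
    """Carry each patient's last weight forward through ``horizon`` days.

    Patients absent from ``weights`` (e.g. never at risk) get weight 1.
    """
    grid = pd.DataFrame(
        {
            "patient_id": np.repeat(patients["patient_id"].to_numpy(), horizon),
            "day": np.tile(np.arange(1, horizon + 1), len(patients)),
        }
    )
    out = grid.merge(weights, on=["patient_id", "day"], how="left")
    cols = ["raw_weight", "stabilized_weight", "truncated_weight"]
    out[cols] = out.groupby("patient_id")[cols].ffill()
    out[cols] = out[cols].fillna(1.0)
    return out
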