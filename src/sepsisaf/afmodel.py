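"""Attributable-fraction estimation from person-period data.

The outcome model is a pooled logistic regression on one row per patient
per hospital day with outcome ``y_t`` = death occurred on or before day t
(cumulative-status coding, the default) or death occurring exactly on day t
among patients still in hospital (discrete-hazard coding, behind a flag).
The time-varying exposure ``sepsis_by_t`` switches on the day *after* the
exposure onset, so same-day onset never explains same-day death status;
clinically relevant events enter the same way.  Both time-varying terms
interact with a cubic polynomial in the hospital day, represented
internally in an orthonormal basis for conditioning and always reported as
contrasts on the raw day scale.

From the fitted model, the day-i odds ratio of death given prior sepsis is
the contrast exp(c_i' beta) with delta-method confidence intervals, and the
daily attributable fraction follows Miettinen's formula

    AF_i = P_c_i * (OR_i - 1) / OR_i,

where P_c_i is the proportion of the deaths accumulated by day i that were
preceded by sepsis.  The period-wide marginal OR and average AF weight the
daily series by the number of deaths occurring each day (alternative
weightings are available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mixedlogit import WeightedMixedLogit, WeightedMixedLogitResults

BASE_COVARIATES = ("age", "charlson", "infection_at_admission")


# ---------------------------------------------------------------------------
# time polynomial basis
# ---------------------------------------------------------------------------
class TimeBasis:
    """Orthonormal cubic polynomial basis over days 1..horizon.

    Columns are the non-constant columns of a QR decomposition of the raw
    Vandermonde matrix [1, t, t^2, t^3]; they span the same cubic space, so
    contrasts evaluated at integer days reproduce the raw-scale polynomial
    exactly while keeping the design well conditioned.
    """

    def __init__(self, horizon: int):
        self.horizon = int(horizon)
        t = np.arange(1, self.horizon + 1, dtype=float)
        V = np.column_stack([np.ones_like(t), t, t**2, t**3])
        Q, R = np.linalg.qr(V)
        # fix signs so that each column is increasing at the right end
        signs = np.sign(Q[-1, :])
        signs[signs == 0] = 1.0
        self._Q = Q * signs
        self._R = R * signs[:, None]

    def evaluate(self, day: np.ndarray | int) -> np.ndarray:
        """Basis values (3 columns) at integer day(s) in 1..horizon."""
        d = np.atleast_1d(np.asarray(day, dtype=int))
        if (d < 1).any() or (d > self.horizon).any():
            raise ValueError(f"day must be in 1..{self.horizon}")
        return self._Q[d - 1, 1:]

    def raw_to_basis(self) -> np.ndarray:
        """Matrix R with raw_poly(t) = [1, P(t)] @ R_inv... (round-trip check)."""
        return self._R


# ---------------------------------------------------------------------------
# person-period construction
# ---------------------------------------------------------------------------
def build_person_period(
    patients: pd.DataFrame,
    exposures: pd.DataFrame,
    weights: pd.DataFrame,
    patient_days: pd.DataFrame,
    horizon: int = 28,
    hazard_coding: bool = False,
    weight_column: str = "truncated_weight",
) -> pd.DataFrame:
    """One row per patient per day with outcome, lagged exposures and weights.

    Cumulative coding (default): every patient contributes days 1..horizon;
    ``y_t`` = 1 iff the patient died on or before day t; covariates freeze
    at the end of hospital stay (no onsets can occur after it) and the last
    in-hospital weight is carried forward.  Hazard coding: rows only while
    in hospital (t <= outcome day), ``y_t`` = 1 on the death day.

    ``sepsis_by_t`` and ``event_by_t`` require onset <= t-1.
    """
    pats = patients.reset_index(drop=True)
    n = len(pats)
    if hazard_coding:
        days_per = np.minimum(pats["outcome_day"].to_numpy(), horizon)
    else:
        days_per = np.full(n, horizon)
    pid = np.repeat(pats["patient_id"].to_numpy(), days_per)
    day = np.concatenate([np.arange(1, d + 1) for d in days_per])
    row = np.repeat(np.arange(n), days_per)

    died = pats["is_case"].to_numpy()
    outcome_day = pats["outcome_day"].to_numpy()
    if hazard_coding:
        y = (died[row] & (day == outcome_day[row])).astype(float)
    else:
        y = (died[row] & (day >= outcome_day[row])).astype(float)

    onset = pats["patient_id"].map(
        exposures.set_index("patient_id")["exposure_onset_day"]
    ).to_numpy()
    sepsis_by_t = (~np.isnan(onset[row])) & (day >= onset[row] + 1)

    ev = patient_days.loc[
        patient_days["clinically_relevant_event"].astype(bool),
        ["patient_id", "day"],
    ]
    first_event = pats["patient_id"].map(ev.groupby("patient_id")["day"].min()).to_numpy()
    event_by_t = (~np.isnan(first_event[row])) & (day >= first_event[row] + 1)

    pp = pd.DataFrame(
        {
            "patient_id": pid,
            "hospital_id": pats["hospital_id"].to_numpy()[row],
            "day": day,
            "y": y,
            "sepsis_by_t": sepsis_by_t.astype(int),
            "event_by_t": event_by_t.astype(int),
            "age": pats["age"].to_numpy()[row],
            "charlson": pats["charlson"].to_numpy()[row],
            "infection_at_admission": pats["infection_at_admission"]
            .astype(int)
            .to_numpy()[row],
        }
    )
    if "admission_category" in pats.columns:
        pp["admission_category"] = pats["admission_category"].to_numpy()[row]

    w = weights.rename(columns={weight_column: "_w"})[["patient_id", "day", "_w"]]
    pp = pp.merge(w, on=["patient_id", "day"], how="left")
    pp["_w"] = pp.groupby("patient_id")["_w"].ffill()
    if pp["_w"].isna().any():
        missing = pp.loc[pp["_w"].isna(), "patient_id"].unique()[:5]
        raise ValueError(
            f"missing weights for in-hospital days of patients {list(missing)}"
        )
    pp = pp.rename(columns={"_w": "ipw"})
    return pp


def build_design(
    pp: pd.DataFrame,
    basis: TimeBasis,
    use_ipw_covariate: bool = True,
    extra_covariates: tuple[str, ...] = (),
    base_covariates: tuple[str, ...] = BASE_COVARIATES,
):
    """Design matrix for the outcome model.

    Returns ``(X, names, sepsis_cols)`` where ``sepsis_cols`` indexes the
    sepsis main effect followed by its three time-interaction columns.
    """
    P = basis.evaluate(pp["day"].to_numpy())
    cols: list[np.ndarray] = [np.ones(len(pp))]
    names = ["const"]
    for c in base_covariates:
        cols.append(pp[c].to_numpy(dtype=float))
        names.append(c)
    if use_ipw_covariate:
        cols.append(pp["ipw"].to_numpy(dtype=float))
        names.append("ipw")
    for c in extra_covariates:
        dummies = pd.get_dummies(pp[c], prefix=c, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(dtype=float))
            names.append(name)
    s = pp["sepsis_by_t"].to_numpy(dtype=float)
    sepsis_start = len(names)
    cols.append(s)
    names.append("sepsis_by_t")
    for j in range(3):
        cols.append(s * P[:, j])
        names.append(f"sepsis_by_t:P{j + 1}")
    e = pp["event_by_t"].to_numpy(dtype=float)
    cols.append(e)
    names.append("event_by_t")
    for j in range(3):
        cols.append(e * P[:, j])
        names.append(f"event_by_t:P{j + 1}")
    X = np.column_stack(cols)
    sepsis_cols = list(range(sepsis_start, sepsis_start + 4))
    return X, names, sepsis_cols


# ---------------------------------------------------------------------------
# Miettinen formula and delta-method intervals
# ---------------------------------------------------------------------------
def miettinen_af(or_i: float, p_c_i: float) -> float:
    """Attributable fraction ``p_c * (OR - 1) / OR``.

    ``p_c`` is the exposure prevalence among the accumulated deaths.  The
    result is bounded above by ``p_c`` and is negative when the exposure is
    protective (OR < 1).
    """
    or_arr = np.asarray(or_i, dtype=float)
    if np.any(or_arr <= 0):
        raise ValueError("odds ratio must be strictly positive")
    p = np.asarray(p_c_i, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_c must lie in [0, 1]")
    out = p * (or_arr - 1.0) / or_arr
    return float(out) if out.ndim == 0 else out


def af_ci_delta(
    or_i: float, var_log_or: float, p_c_i: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Delta-method confidence interval for the attributable fraction.

    Writing AF = p_c * (1 - exp(-logOR)), the derivative with respect to
    logOR is ``p_c * exp(-logOR) = p_c / OR``, so
    Var(AF) ~= (p_c / OR)^2 * Var(logOR).  ``p_c`` is treated as a known
    constant (its sampling variation is ignored).
    """
    if var_log_or < 0:
        raise ValueError("var_log_or must be non-negative")
    af = miettinen_af(or_i, p_c_i)
    se = (p_c_i / or_i) * np.sqrt(var_log_or)
    z = norm.ppf(1.0 - alpha / 2.0)
    return af - z * se, af + z * se


def p_c_series(cases: pd.DataFrame, exposures: pd.DataFrame, horizon: int) -> np.ndarray:
    """Proportion of accumulated deaths preceded by sepsis, per day.

    ``P_c_i`` = (# cases dead by day i with exposure onset <= i-1) /
    (# cases dead by day i), defined as 0 while no deaths have occurred.
    """
    death_day = cases["outcome_day"].to_numpy()
    onset = (
        cases["patient_id"]
        .map(exposures.set_index("patient_id")["exposure_onset_day"])
        .to_numpy()
    )
    out = np.zeros(horizon)
    for i in range(1, horizon + 1):
        dead = death_day <= i
        denom = dead.sum()
        if denom == 0:
            continue
        num = (dead & ~np.isnan(onset) & (onset <= i - 1)).sum()
        out[i - 1] = num / denom
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------
@dataclass
class _ContrastFit:
    """Minimal coefficient/covariance view used for contrast arithmetic."""

    params: np.ndarray
    cov: np.ndarray
    sepsis_cols: list[int]
    basis: TimeBasis

    def contrast_vector(self, day: int) -> np.ndarray:
        c = np.zeros(len(self.params))
        c[self.sepsis_cols[0]] = 1.0
        c[self.sepsis_cols[1:]] = self.basis.evaluate(day)[0]
        return c


def daily_odds_ratio(
    fit: _ContrastFit, day: int, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Odds ratio of death by ``day`` given prior sepsis, with delta CI.

    Returns ``(or, (lo, hi), var_log_or)``.
    """
    c = fit.contrast_vector(int(day))
    log_or = float(c @ fit.params)
    var = float(c @ fit.cov @ c)
    z = norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(var)
    return np.exp(log_or), (np.exp(log_or - z * se), np.exp(log_or + z * se)), var


def average_af(
    fit: _ContrastFit,
    p_c: np.ndarray,
    death_counts: np.ndarray,
    weighting: str = "deaths",
    alpha: float = 0.05,
) -> dict:
    """Period-wide marginal OR and average AF with delta-method intervals.

    ``weighting`` selects how daily quantities are pooled:

    * ``"deaths"`` (default): weight day i by the number of deaths
      occurring on day i;
    * ``"days"``: equal weight per day;
    * ``"marginal_contrast"``: evaluate a single death-weighted contrast
      and apply the Miettinen formula once at the pooled P_c.
    """
    horizon = fit.basis.horizon
    d = np.asarray(death_counts, dtype=float)
    if d.shape != (horizon,):
        raise ValueError("death_counts must have one entry per day")
    if weighting == "days":
        v = np.ones(horizon)
    elif weighting in ("deaths", "marginal_contrast"):
        if d.sum() == 0:
            raise ValueError("no deaths in the period; average AF undefined")
        v = d
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    v = v / v.sum()

    C = np.stack([fit.contrast_vector(i) for i in range(1, horizon + 1)])
    log_or_days = C @ fit.params
    c_bar = v @ C
    marg_log_or = float(c_bar @ fit.params)
    var_marg = float(c_bar @ fit.cov @ c_bar)
    z = norm.ppf(1.0 - alpha / 2.0)
    marginal_or = float(np.exp(marg_log_or))
    or_ci = (
        float(np.exp(marg_log_or - z * np.sqrt(var_marg))),
        float(np.exp(marg_log_or + z * np.sqrt(var_marg))),
    )

    p_c = np.asarray(p_c, dtype=float)
    if weighting == "marginal_contrast":
        p_bar = float(v @ p_c)
        af = miettinen_af(marginal_or, p_bar)
        grad = (p_bar / marginal_or) * c_bar
    else:
        af_days = p_c * (1.0 - np.exp(-log_or_days))
        af = float(v @ af_days)
        # gradient of the weighted AF sum with respect to beta
        grad = (v * p_c * np.exp(-log_or_days)) @ C
    var_af = float(grad @ fit.cov @ grad)
    af_ci = (af - z * np.sqrt(var_af), af + z * np.sqrt(var_af))
    return {
        "marginal_or": marginal_or,
        "marginal_or_ci": or_ci,
        "average_af": float(af),
        "average_af_ci": af_ci,
        "weighting": weighting,
    }


class AttributableFractionModel:
    """Pooled logistic attributable-fraction model on person-period data.

    Parameters
    ----------
    person_period : output of :func:`build_person_period`.
    horizon : last hospital day modelled (default 28).
    use_ipw_covariate : include the weight value also as a covariate, as in
        the motivating analysis; set False to use it only as a weight.
    hazard_coding : the person-period table was built with discrete-hazard
        coding (affects only bookkeeping; the design is identical).
    random_intercept : include a Gaussian hospital-level random intercept.
    extra_covariates : names of categorical columns (e.g.
        ``admission_category``) added as dummy covariates.
    """

    def __init__(
        self,
        person_period: pd.DataFrame,
        horizon: int = 28,
        use_ipw_covariate: bool = True,
        hazard_coding: bool = False,
        random_intercept: bool = True,
        extra_covariates: tuple[str, ...] = (),
        base_covariates: tuple[str, ...] = BASE_COVARIATES,
    ):
        self.pp = person_period
        self.horizon = int(horizon)
        self.basis = TimeBasis(self.horizon)
        self.hazard_coding = bool(hazard_coding)
        self.random_intercept = bool(random_intercept)
        X, names, sepsis_cols = build_design(
            person_period,
            self.basis,
            use_ipw_covariate=use_ipw_covariate,
            extra_covariates=extra_covariates,
            base_covariates=base_covariates,
        )
        self._X = X
        self._names = names
        self._sepsis_cols = sepsis_cols

    def fit(self, n_quad: int = 7, **kwargs) -> "AttributableFractionResults":
        model = WeightedMixedLogit(
            self.pp["y"].to_numpy(),
            self._X,
            self.pp["hospital_id"].to_numpy(),
            weights=self.pp["ipw"].to_numpy(),
            exog_names=self._names,
        )
        if not self.random_intercept:
            kwargs.setdefault("group_var", 0.0)
        res = model.fit(n_quad=n_quad, **kwargs)
        return AttributableFractionResults(self, res)


class AttributableFractionResults:
    """Daily odds ratios, attributable fractions and period summaries."""

    def __init__(self, model: AttributableFractionModel, fit: WeightedMixedLogitResults):
        self.model = model
        self.model_fit = fit
        self._contrast = _ContrastFit(
            params=fit.params,
            cov=fit.cov_params(),
            sepsis_cols=model._sepsis_cols,
            basis=model.basis,
        )
        pp = model.pp
        last = pp.sort_values("day").groupby("patient_id").tail(1)
        if model.hazard_coding:
            died = last["y"] == 1
            death_day = last["day"]
        else:
            died = last["y"] == 1
            first_dead = (
                pp[pp["y"] == 1].groupby("patient_id")["day"].min().rename("dd")
            )
            death_day = last["patient_id"].map(first_dead)
        cases = pd.DataFrame(
            {
                "patient_id": last["patient_id"].to_numpy(),
                "outcome_day": death_day.to_numpy(),
            }
        )[died.to_numpy()]
        onset_day = (
            pp[pp["sepsis_by_t"] == 1].groupby("patient_id")["day"].min() - 1
        )
        self._cases = cases
        self._exposures = onset_day.rename("exposure_onset_day").reset_index()
        self.p_c = p_c_series(cases, self._exposures, model.horizon)
        self.death_counts = np.bincount(
            cases["outcome_day"].astype(int).clip(upper=model.horizon),
            minlength=model.horizon + 1,
        )[1:]

    def daily_effects(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-day OR, P_c and AF with delta-method confidence intervals."""
        rows = []
        for i in range(1, self.model.horizon + 1):
            or_i, (lo, hi), var = daily_odds_ratio(self._contrast, i, alpha)
            p_c = self.p_c[i - 1]
            af = miettinen_af(or_i, p_c)
            af_lo, af_hi = af_ci_delta(or_i, var, p_c, alpha)
            rows.append(
                {
                    "day": i,
                    "or": or_i,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                    "p_c": p_c,
                    "af": af,
                    "af_ci_low": af_lo,
                    "af_ci_high": af_hi,
                }
            )
        return pd.DataFrame(rows)

    def marginal(self, weighting: str = "deaths", alpha: float = 0.05) -> dict:
        """Period-wide marginal OR and average AF."""
        return average_af(
            self._contrast, self.p_c, self.death_counts, weighting, alpha
        )

    def summary(self) -> str:
        marg = self.marginal()
        head = [
            "Attributable fraction of in-hospital death due to nosocomial sepsis",
            f"horizon: {self.model.horizon} days   coding: "
            + ("discrete-hazard" if self.model.hazard_coding else "cumulative-status"),
            f"marginal OR: {marg['marginal_or']:.3f} "
            f"(95% CI {marg['marginal_or_ci'][0]:.3f}-{marg['marginal_or_ci'][1]:.3f})",
            f"average AF: {marg['average_af']:.4f} "
            f"(95% CI {marg['average_af_ci'][0]:.4f}-{marg['average_af_ci'][1]:.4f})",
            "",
        ]
        return "\n".join(head) + self.model_fit.summary()
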