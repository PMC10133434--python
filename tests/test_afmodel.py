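"""Person-period construction, daily odds-ratio contrasts, Miettinen
arithmetic and delta-method intervals."""

import numpy as np
import pandas as pd
import pytest

from sepsisaf.afmodel import (
    TimeBasis,
    _ContrastFit,
    af_ci_delta,
    average_af,
    build_person_period,
    daily_odds_ratio,
    miettinen_af,
    p_c_series,
)


def _patients(rows):
    df = pd.DataFrame(rows)
    df["hospital_id"] = 1
    df["age"] = 60.0
    df["charlson"] = 1
    df["infection_at_admission"] = False
    return df


def _unit_weights(patients, horizon=28):
    return pd.DataFrame(
        {
            "patient_id": np.repeat(patients["patient_id"].to_numpy(), horizon),
            "day": np.tile(np.arange(1, horizon + 1), len(patients)),
            "truncated_weight": 1.0,
        }
    )


def _days(pid, n, event_day=None):
    return [
        {
            "patient_id": pid,
            "day": d,
            "clinically_relevant_event": d == event_day,
        }
        for d in range(1, n + 1)
    ]


def test_person_period_case_with_onset():
    """A patient dying day 5 with sepsis onset day 3 has y_t = 1 from day 5
    and the lagged exposure indicator on from day 4."""
    pats = _patients(
        [{"patient_id": 1, "outcome_day": 5, "is_case": True}]
    )
    expo = pd.DataFrame({"patient_id": [1], "exposure_onset_day": [3]})
    pp = build_person_period(
        pats, expo, _unit_weights(pats), pd.DataFrame(_days(1, 5))
    )
    assert len(pp) == 28
    assert (pp.loc[pp["day"] >= 5, "y"] == 1).all()
    assert (pp.loc[pp["day"] < 5, "y"] == 0).all()
    assert (pp.loc[pp["day"] >= 4, "sepsis_by_t"] == 1).all()
    assert (pp.loc[pp["day"] < 4, "sepsis_by_t"] == 0).all()


def test_person_period_discharged_control():
    pats = _patients(
        [{"patient_id": 2, "outcome_day": 4, "is_case": False}]
    )
    expo = pd.DataFrame({"patient_id": [], "exposure_onset_day": []})
    pp = build_person_period(
        pats, expo, _unit_weights(pats), pd.DataFrame(_days(2, 4))
    )
    assert (pp["y"] == 0).all()
    assert (pp["sepsis_by_t"] == 0).all()


def test_person_period_hazard_coding_stops_at_outcome():
    pats = _patients(
        [
            {"patient_id": 1, "outcome_day": 5, "is_case": True},
            {"patient_id": 2, "outcome_day": 3, "is_case": False},
        ]
    )
    expo = pd.DataFrame({"patient_id": [], "exposure_onset_day": []})
    days = pd.DataFrame(_days(1, 5) + _days(2, 3))
    pp = build_person_period(
        pats, expo, _unit_weights(pats), days, hazard_coding=True
    )
    assert pp.groupby("patient_id")["day"].max().tolist() == [5, 3]
    assert pp["y"].sum() == 1
    assert pp.loc[(pp["patient_id"] == 1) & (pp["day"] == 5), "y"].item() == 1


def test_monotone_indicators_on_simulated_population(recovery_cohort):
    from sepsisaf.definitions import apply_definition, classify_cohort

    pats = recovery_cohort.patients.head(300)
    eps = classify_cohort(recovery_cohort.patient_days)
    expo = apply_definition(eps, "main")
    pp = build_person_period(
        pats,
        expo,
        _unit_weights(pats),
        recovery_cohort.patient_days,
    )
    for col in ("y", "sepsis_by_t", "event_by_t"):
        diffs = pp.sort_values(["patient_id", "day"]).groupby("patient_id")[col].diff()
        assert (diffs.dropna() >= 0).all(), col


def test_missing_weight_raises():
    pats = _patients([{"patient_id": 1, "outcome_day": 5, "is_case": True}])
    expo = pd.DataFrame({"patient_id": [], "exposure_onset_day": []})
    w = _unit_weights(pats).iloc[5:]  # weights missing from day 1
    with pytest.raises(ValueError, match="weight"):
        build_person_period(pats, expo, w, pd.DataFrame(_days(1, 5)))


# ---------------------------------------------------------------------------
# time basis and contrasts
# ---------------------------------------------------------------------------
def test_basis_spans_raw_cubic_exactly():
    """Any raw cubic in the day is represented exactly by the orthonormal
    basis plus constant (round trip through least squares)."""
    basis = TimeBasis(28)
    t = np.arange(1, 29, dtype=float)
    raw = 0.3 - 0.05 * t + 0.002 * t**2 - 3e-5 * t**3
    design = np.column_stack([np.ones(28), basis.evaluate(t.astype(int))])
    coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
    assert np.allclose(design @ coef, raw, atol=1e-12)


def _fit_from(beta, cov, horizon=28):
    basis = TimeBasis(horizon)
    return _ContrastFit(
        params=np.asarray(beta, float),
        cov=np.asarray(cov, float),
        sepsis_cols=[0, 1, 2, 3],
        basis=basis,
    )


def test_zero_interactions_give_constant_or():
    fit = _fit_from([0.5, 0, 0, 0], np.zeros((4, 4)))
    ors = [daily_odds_ratio(fit, i)[0] for i in (1, 10, 28)]
    assert np.allclose(ors, np.exp(0.5))


def test_hand_set_linear_trend_matches_arithmetic():
    """With main effect 0.5 and raw linear slope 0.01/day the day-10 log OR
    is 0.6; the orthonormal coefficients are obtained by projecting the raw
    polynomial onto the basis."""
    basis = TimeBasis(28)
    t = np.arange(1, 29, dtype=float)
    raw = 0.5 + 0.01 * t
    design = np.column_stack([np.ones(28), basis.evaluate(t.astype(int))])
    coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
    fit = _fit_from(coef, np.zeros((4, 4)))
    or10, (lo, hi), var = daily_odds_ratio(fit, 10)
    assert or10 == pytest.approx(np.exp(0.6), rel=1e-10)
    assert lo == pytest.approx(or10) and hi == pytest.approx(or10)
    assert var == 0.0


def test_day_out_of_range_raises():
    fit = _fit_from([0.5, 0, 0, 0], np.zeros((4, 4)))
    with pytest.raises(ValueError):
        daily_odds_ratio(fit, 29)
    with pytest.raises(ValueError):
        daily_odds_ratio(fit, 0)


def test_delta_ci_matches_parametric_bootstrap():
    """The delta-method CI width for a daily OR agrees with a 2000-draw
    parametric bootstrap of the coefficient vector within 5%."""
    rng = np.random.default_rng(0)
    A = rng.normal(size=(4, 4)) * 0.05
    cov = A @ A.T + 0.01 * np.eye(4)
    beta = np.array([0.4, 0.1, -0.05, 0.02])
    fit = _fit_from(beta, cov)
    or14, (lo, hi), var = daily_odds_ratio(fit, 14)
    c = fit.contrast_vector(14)
    draws = rng.multivariate_normal(beta, cov, size=2000) @ c
    boot = np.exp(np.quantile(draws, [0.025, 0.975]))
    assert np.log(hi / lo) == pytest.approx(np.log(boot[1] / boot[0]), rel=0.05)


# ---------------------------------------------------------------------------
# Miettinen / AF arithmetic
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "orv,pc,expected",
    [
        (1.0, 0.3, 0.0),
        (2.0, 0.5, 0.25),
        (1.73, 0.1801, 0.0760),
        (0.5, 0.2, -0.2),
    ],
)
def test_miettinen_values(orv, pc, expected):
    assert miettinen_af(orv, pc) == pytest.approx(expected, abs=5e-5)


def test_miettinen_domain_and_bounds():
    with pytest.raises(ValueError):
        miettinen_af(0.0, 0.3)
    with pytest.raises(ValueError):
        miettinen_af(2.0, 1.3)
    # AF <= p_c for harmful exposure and approaches p_c as OR grows
    assert miettinen_af(1e9, 0.4) == pytest.approx(0.4, abs=1e-8)
    for orv in (1.1, 2.0, 10.0):
        assert miettinen_af(orv, 0.4) <= 0.4


def test_af_delta_ci_hand_arithmetic():
    lo, hi = af_ci_delta(2.0, 0.04, 0.5)
    # 1.96 is the rounded normal quantile; the code uses the exact one
    assert (lo, hi) == pytest.approx((0.25 - 1.96 * 0.05, 0.25 + 1.96 * 0.05), abs=1e-4)
    lo0, hi0 = af_ci_delta(2.0, 0.0, 0.5)
    assert lo0 == hi0 == pytest.approx(0.25)


def test_af_delta_ci_matches_monte_carlo_propagation():
    rng = np.random.default_rng(1)
    orv, var, pc = 1.8, 0.03, 0.3
    lo, hi = af_ci_delta(orv, var, pc)
    draws = pc * (1 - np.exp(-rng.normal(np.log(orv), np.sqrt(var), 10_000)))
    mc_lo, mc_hi = np.quantile(draws, [0.025, 0.975])
    assert (hi - lo) == pytest.approx(mc_hi - mc_lo, rel=0.05)


def test_p_c_series_hand_count():
    cases = pd.DataFrame({"patient_id": [1, 2, 3], "outcome_day": [2, 5, 9]})
    expo = pd.DataFrame({"patient_id": [2], "exposure_onset_day": [3]})
    pc = p_c_series(cases, expo, horizon=10)
    assert pc[4] == pytest.approx(1 / 2)  # day 5: deaths {1,2}, exposed {2}
    assert pc[8] == pytest.approx(1 / 3)  # day 9: all three dead
    assert pc[0] == 0.0
    assert ((pc >= 0) & (pc <= 1)).all()


def test_p_c_zero_when_no_exposed_cases():
    cases = pd.DataFrame({"patient_id": [1, 2], "outcome_day": [2, 5]})
    expo = pd.DataFrame({"patient_id": [], "exposure_onset_day": []})
    assert (p_c_series(cases, expo, 28) == 0).all()


# ---------------------------------------------------------------------------
# average AF
# ---------------------------------------------------------------------------
def test_constant_series_collapses_to_single_miettinen():
    fit = _fit_from([np.log(2.0), 0, 0, 0], np.zeros((4, 4)))
    deaths = np.zeros(28)
    deaths[[5, 10]] = [10, 20]
    out = average_af(fit, np.full(28, 0.4), deaths)
    assert out["marginal_or"] == pytest.approx(2.0)
    assert out["average_af"] == pytest.approx(miettinen_af(2.0, 0.4))


def test_two_day_hand_weighted_average():
    """OR (2, 4) on the two death days with 10 and 30 deaths and P_c = 0.5
    gives marginal logOR = (10 ln2 + 30 ln4)/40 and average AF = 0.34375."""
    basis = TimeBasis(28)
    t = np.arange(1, 29, dtype=float)
    # raw log-OR profile hitting ln2 at day 3 and ln4 at day 7 (linear)
    slope = (np.log(4) - np.log(2)) / 4.0
    raw = np.log(2) + slope * (t - 3.0)
    design = np.column_stack([np.ones(28), basis.evaluate(t.astype(int))])
    coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
    fit = _fit_from(coef, np.zeros((4, 4)))
    deaths = np.zeros(28)
    deaths[2], deaths[6] = 10, 30
    out = average_af(fit, np.full(28, 0.5), deaths)
    assert np.log(out["marginal_or"]) == pytest.approx(
        (10 * np.log(2) + 30 * np.log(4)) / 40
    )
    assert out["average_af"] == pytest.approx((10 * 0.25 + 30 * 0.375) / 40)


def test_all_zero_death_counts_raise():
    fit = _fit_from([0.1, 0, 0, 0], np.zeros((4, 4)))
    with pytest.raises(ValueError):
        average_af(fit, np.full(28, 0.2), np.zeros(28))


def test_weighting_options_differ_for_nonconstant_series():
    fit = _fit_from([0.2, 0.3, 0.1, 0.0], 0.01 * np.eye(4))
    deaths = np.linspace(1, 5, 28)
    pc = np.linspace(0.05, 0.4, 28)
    outs = {
        w: average_af(fit, pc, deaths, weighting=w)
        for w in ("deaths", "days", "marginal_contrast")
    }
    assert outs["deaths"]["average_af"] != outs["days"]["average_af"]
    # marginal-contrast applies the formula once at the pooled values
    assert outs["marginal_contrast"]["marginal_or"] == pytest.approx(
        outs["deaths"]["marginal_or"]
    )
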