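"""Rule-based sepsis phenotyping: organ dysfunction, probability tiers,
episodes, the nosocomial rule, and the SOFA-increase definition.

A hospital day *qualifies* when at least one acute organ-failure criterion
is met.  Qualifying days are graded by antibiotic use, culture results and
co-occurring clinically relevant events into four probability tiers
(definitive > very probable > probable > possible); consecutive qualifying
days form an episode.  An episode is nosocomial only when it starts on
hospital day 3 or later.  Four exposure definitions are supported:

``main``
    antibiotic use + organ failure + no clinically relevant event the same
    day + suspected source recorded (tiers: definitive or very probable
    without a same-day event).
``alt1``
    definitive, very probable, or probable tier.
``alt2``
    definitive or very probable tier.
``sofa``
    first day >= 3 with a SOFA total at least 2 points above the admission
    (day 1) value and a new antibiotic started, ignoring events.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import NOSOCOMIAL_MIN_ONSET_DAY

DYSFUNCTION_SYSTEMS = (
    "cardiovascular",
    "respiratory",
    "neurologic",
    "renal",
    "hepatic",
    "hematologic",
    "coagulation",
)

#: tier order, most to least certain
TIERS = ("definitive", "very_probable", "probable", "possible")
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}

DEFINITIONS = ("main", "alt1", "alt2", "sofa")


class DataConsistencyWarning(UserWarning):
    """Input pattern that contradicts the data-collection rules."""


def _col(df: pd.DataFrame, name: str, default=np.nan) -> pd.Series:
    if name in df.columns:
        return df[name]
    return pd.Series(default, index=df.index)


def detect_organ_dysfunction(obs: pd.DataFrame) -> pd.DataFrame:
    """Seven acute organ-failure flags per observation row.

    A missing measurement never triggers a criterion (comparisons with
    missing values are false).  Coagulation abnormality does not count
    while the patient is on an anticoagulant.
    """
    flags = pd.DataFrame(index=obs.index)
    flags["cardiovascular"] = (
        _col(obs, "systolic_bp").lt(90)
        | _col(obs, "mean_ap").lt(65)
        | _col(obs, "sbp_drop").gt(40)
    )
    flags["respiratory"] = _col(obs, "pf_ratio").lt(300) | _col(
        obs, "on_supplemental_o2_for_spo2", False
    ).fillna(False).astype(bool)
    flags["neurologic"] = (
        _col(obs, "mental_status_abnormal", False).fillna(False).astype(bool)
    )
    flags["renal"] = _col(obs, "creatinine").ge(2) | _col(
        obs, "low_urine_output_2h", False
    ).fillna(False).astype(bool)
    flags["hepatic"] = _col(obs, "bilirubin").gt(2)
    flags["hematologic"] = _col(obs, "platelets").lt(100_000)
    on_ac = _col(obs, "on_anticoagulant", False).fillna(False).astype(bool)
    flags["coagulation"] = (
        _col(obs, "inr").gt(1.5) | _col(obs, "aptt").gt(60)
    ) & ~on_ac
    return flags.astype(bool)


def classify_day(
    obs: pd.DataFrame,
    dysfunction: pd.DataFrame | None = None,
    require_source: bool = True,
) -> pd.DataFrame:
    """Grade each observation day into a sepsis probability tier.

    Returns a frame with columns ``tier`` (pandas category in ``TIERS``
    order, NaN when the day does not qualify) and ``meets_main_definition``.

    Grading of days with >= 1 organ dysfunction:

    * antibiotic active, positive culture, no event  -> definitive
    * antibiotic active, any other culture/event mix -> very probable
    * no antibiotic, no event                        -> probable
    * no antibiotic, event                           -> possible

    Cultures are only collected under antibiotics; a recorded culture
    without antibiotic use raises :class:`DataConsistencyWarning` and the
    culture is ignored.  A culture that was simply not collected on an
    antibiotic day is graded like a negative one.  When ``require_source``
    is set (default), the antibiotic-based tiers (definitive/very probable)
    and the main definition additionally require the suspected infection
    source to be recorded; an antibiotic day without source information is
    left ungraded.
    """
    if dysfunction is None:
        dysfunction = detect_organ_dysfunction(obs)
    any_dysf = dysfunction.any(axis=1).to_numpy()
    abx = _col(obs, "antibiotic_active", False).fillna(False).astype(bool).to_numpy()
    event = (
        _col(obs, "clinically_relevant_event", False)
        .fillna(False)
        .astype(bool)
        .to_numpy()
    )
    culture = _col(obs, "culture_result", "not_collected").fillna("not_collected")
    culture = culture.astype(str).to_numpy()
    source = (
        _col(obs, "suspected_source_recorded", False)
        .fillna(False)
        .astype(bool)
        .to_numpy()
    )

    bad_culture = ~abx & (culture != "not_collected")
    if bad_culture.any():
        warnings.warn(
            f"{int(bad_culture.sum())} day(s) report a culture result without "
            "antibiotic use; cultures are only collected under antibiotics "
            "and were ignored for grading",
            DataConsistencyWarning,
            stacklevel=2,
        )

    source_ok = source if require_source else np.ones_like(source)

    tier = np.full(len(obs), None, dtype=object)
    graded_abx = any_dysf & abx & source_ok
    tier[graded_abx & (culture == "positive") & ~event] = "definitive"
    tier[graded_abx & ~((culture == "positive") & ~event)] = "very_probable"
    tier[any_dysf & ~abx & ~event] = "probable"
    tier[any_dysf & ~abx & event] = "possible"

    out = pd.DataFrame(index=obs.index)
    out["tier"] = pd.Categorical(tier, categories=list(TIERS), ordered=True)
    out["meets_main_definition"] = graded_abx & ~event
    return out


def build_episodes(
    classified_days: pd.DataFrame, episode_gap: int = 2
) -> pd.DataFrame:
    """Merge consecutive qualifying days into sepsis episodes.

    ``classified_days`` needs columns ``patient_id``, ``day``, ``tier`` and
    ``meets_main_definition``; within each patient the days must be sorted
    and unique.  A run of qualifying days separated by gaps of fewer than
    ``episode_gap`` non-qualifying days forms one episode; the episode tier
    is the highest tier attained on any of its days.  Episodes are
    nosocomial when they start on day >= 3.
    """
    if int(episode_gap) < 1:
        raise ValueError("episode_gap must be at least 1")
    q = classified_days[classified_days["tier"].notna()].copy()
    if q.empty:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "onset_day",
                "end_day",
                "tier",
                "meets_main_definition",
                "nosocomial",
            ]
        )
    grouped = q.groupby("patient_id", sort=True)
    if (grouped["day"].diff().dropna() <= 0).any():
        raise ValueError("days must be strictly increasing within each patient")

    q["_gap"] = grouped["day"].diff().sub(1).fillna(0)
    q["_episode"] = (q["_gap"] >= episode_gap).groupby(q["patient_id"]).cumsum()
    q["_rank"] = q["tier"].map(_TIER_RANK)
    agg = (
        q.groupby(["patient_id", "_episode"], sort=True)
        .agg(
            onset_day=("day", "min"),
            end_day=("day", "max"),
            _best=("_rank", "min"),
            meets_main_definition=("meets_main_definition", "any"),
        )
        .reset_index()
    )
    agg["tier"] = pd.Categorical(
        [TIERS[int(r)] for r in agg["_best"]], categories=list(TIERS), ordered=True
    )
    agg["nosocomial"] = agg["onset_day"] >= NOSOCOMIAL_MIN_ONSET_DAY
    return agg[
        [
            "patient_id",
            "onset_day",
            "end_day",
            "tier",
            "meets_main_definition",
            "nosocomial",
        ]
    ]


def sofa_score(obs: pd.DataFrame) -> pd.DataFrame:
    """Six-system SOFA subscores and total per observation row.

    The banding follows the standard published scale where the collected
    variables permit; vasopressor dose and ventilation are not collected,
    so cardiovascular scores through MAP only (ceiling 1) and respiratory
    through the P/F ratio bands.  The mental-status flag maps to a CNS
    subscore of 2; missing measurements score 0.
    """
    out = pd.DataFrame(index=obs.index)
    pf = _col(obs, "pf_ratio")
    out["respiratory"] = (
        pf.lt(400).astype(int)
        + pf.lt(300).astype(int)
        + pf.lt(200).astype(int)
        + pf.lt(100).astype(int)
    )
    plt = _col(obs, "platelets")
    out["coagulation"] = (
        plt.lt(150_000).astype(int)
        + plt.lt(100_000).astype(int)
        + plt.lt(50_000).astype(int)
        + plt.lt(20_000).astype(int)
    )
    bili = _col(obs, "bilirubin")
    out["hepatic"] = (
        bili.ge(1.2).astype(int)
        + bili.ge(2.0).astype(int)
        + bili.ge(6.0).astype(int)
        + bili.ge(12.0).astype(int)
    )
    out["cardiovascular"] = _col(obs, "mean_ap").lt(70).astype(int)
    out["neurologic"] = (
        _col(obs, "mental_status_abnormal", False).fillna(False).astype(bool)
    ).astype(int) * 2
    cr = _col(obs, "creatinine")
    out["renal"] = (
        cr.ge(1.2).astype(int)
        + cr.ge(2.0).astype(int)
        + cr.ge(3.5).astype(int)
        + cr.ge(5.0).astype(int)
    )
    out["sofa_total"] = out.sum(axis=1)
    return out


def _sofa_exposure(patient_days: pd.DataFrame) -> pd.Series:
    """First qualifying day under the SOFA-increase definition, per patient."""
    scores = sofa_score(patient_days)
    df = patient_days[["patient_id", "day"]].copy()
    df["sofa_total"] = scores["sofa_total"].to_numpy()
    df["new_abx"] = (
        _col(patient_days, "new_antibiotic_started", False)
        .fillna(False)
        .astype(bool)
        .to_numpy()
    )
    baseline = (
        df[df["day"] == 1].set_index("patient_id")["sofa_total"].rename("baseline")
    )
    df = df.join(baseline, on="patient_id")
    df["baseline"] = df["baseline"].fillna(0)
    hit = df[
        (df["day"] >= NOSOCOMIAL_MIN_ONSET_DAY)
        & (df["sofa_total"] >= df["baseline"] + 2)
        & df["new_abx"]
    ]
    return hit.groupby("patient_id")["day"].min()


def apply_definition(
    episodes: pd.DataFrame,
    definition: str,
    patient_days: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-patient exposure onset day under one of the four definitions.

    Returns a frame with columns ``patient_id``, ``definition`` and
    ``exposure_onset_day`` containing only exposed patients.  Episodes with
    onset on days 1-2 never contribute (community-acquired).  ``sofa``
    requires ``patient_days`` for score computation.
    """
    if definition not in DEFINITIONS:
        raise ValueError(
            f"unknown definition {definition!r}; expected one of {DEFINITIONS}"
        )
    if definition == "sofa":
        if patient_days is None:
            raise ValueError("the sofa definition requires patient_days")
        onsets = _sofa_exposure(patient_days)
    else:
        noso = episodes[episodes["nosocomial"]]
        if definition == "main":
            keep = noso[noso["meets_main_definition"]]
        elif definition == "alt1":
            keep = noso[
                noso["tier"].isin(["definitive", "very_probable", "probable"])
            ]
        else:  # alt2
            keep = noso[noso["tier"].isin(["definitive", "very_probable"])]
        onsets = keep.groupby("patient_id")["onset_day"].min()
    out = onsets.rename("exposure_onset_day").reset_index()
    out.insert(1, "definition", definition)
    return out


def classify_cohort(
    patient_days: pd.DataFrame,
    episode_gap: int = 2,
    require_source: bool = True,
) -> pd.DataFrame:
    """Run day grading and episode construction over a long patient-day table."""
    graded = classify_day(patient_days, require_source=require_source)
    days = patient_days[["patient_id", "day"]].copy()
    days["tier"] = graded["tier"].to_numpy()
    days["meets_main_definition"] = graded["meets_main_definition"].to_numpy()
    return build_episodes(days, episode_gap=episode_gap)
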