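"""Simulation configuration for synthetic hospital cohorts.

The defaults describe a plausible operating point for a middle-income-country
hospital population: mostly medical admissions, mean age 63 (SD 18.6),
Charlson-like comorbidity counts around 2, a median length of stay near one
week, low daily hospital mortality, and a nosocomial sepsis prevalence in
survivors of a few percent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

ADMISSION_TYPES = ("medical", "elective_surgery", "urgent_surgery")
ADMISSION_CATEGORIES = (
    "neurological",
    "cardiovascular",
    "infection",
    "renal",
    "abdominal",
    "other",
)

#: first hospital day on which an infection counts as hospital-acquired
NOSOCOMIAL_MIN_ONSET_DAY = 3


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= float(value) <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass
class SepsisHazard:
    """Daily hazard of first sepsis onset, on the log-odds scale.

    ``base`` is the per-day onset probability for a reference patient
    (age at the cohort mean, Charlson 0, no prior clinically relevant
    event); the remaining fields are log-odds coefficients.
    """

    base: float = 0.006
    age: float = 0.01  # per year above the cohort mean age
    charlson: float = 0.08  # per comorbidity point
    event: float = 0.7  # prior clinically relevant event

    def validate(self) -> None:
        _check_prob("daily_sepsis_hazard.base", self.base)
        for name in ("age", "charlson", "event"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"daily_sepsis_hazard.{name} must be finite")


@dataclass
class DeathHazard:
    """Daily in-hospital death hazard on the log-odds scale."""

    base: float = 0.004
    age: float = 0.03  # per year above the cohort mean age
    charlson: float = 0.12  # per comorbidity point
    infection: float = 0.5  # infection present at admission

    def validate(self) -> None:
        _check_prob("baseline_death_hazard.base", self.base)
        for name in ("age", "charlson", "infection"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"baseline_death_hazard.{name} must be finite")


@dataclass
class SimulationConfig:
    n_hospitals: int = 20
    patients_per_hospital: int = 100
    horizon_days: int = 28
    #: P(medical), P(elective surgery), P(urgent surgery); must sum to 1
    admission_mix: tuple[float, float, float] = (0.849, 0.083, 0.068)
    age_mean: float = 63.0
    age_sd: float = 18.6
    #: mean of the Poisson comorbidity count
    charlson_rate: float = 2.0
    baseline_infection_prob: float = 0.33
    daily_sepsis_hazard: SepsisHazard = field(default_factory=SepsisHazard)
    daily_event_hazard: float = 0.02
    #: true log odds ratio of death given (lagged) nosocomial sepsis.  A
    #: scalar gives a constant effect; a length-4 sequence (c0, c1, c2, c3)
    #: gives the cubic day polynomial c0 + c1*t + c2*t^2 + c3*t^3.
    sepsis_mortality_log_or: float | Sequence[float] = 1.0
    baseline_death_hazard: DeathHazard = field(default_factory=DeathHazard)
    discharge_hazard: float = 0.09
    #: multiplies the discharge hazard while a sepsis episode is active
    discharge_hazard_ratio_sepsis: float = 0.3
    #: SD of the centre-level random intercept on the death log-odds
    center_sd: float = 0.3
    culture_positive_prob: float = 0.4
    antibiotic_given_sepsis_prob: float = 0.9
    source_recorded_prob: float = 0.95
    #: chance that a non-septic hospital day shows one spurious organ
    #: dysfunction (produces probable/possible tier days)
    spurious_dysfunction_prob: float = 0.02
    #: number of consecutive qualifying days a generated episode lasts
    sepsis_duration_days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.daily_sepsis_hazard, dict):
            self.daily_sepsis_hazard = SepsisHazard(**self.daily_sepsis_hazard)
        if isinstance(self.baseline_death_hazard, dict):
            self.baseline_death_hazard = DeathHazard(**self.baseline_death_hazard)
        if isinstance(self.admission_mix, list):
            self.admission_mix = tuple(self.admission_mix)

    # -- validation ----------------------------------------------------
    def validate(self) -> "SimulationConfig":
        for name in ("n_hospitals", "patients_per_hospital"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if int(self.horizon_days) < 3:
            raise ConfigError("horizon_days must be at least 3")
        mix = np.asarray(self.admission_mix, dtype=float)
        if mix.shape != (3,):
            raise ConfigError("admission_mix must have exactly three entries")
        if (mix < 0).any() or (mix > 1).any():
            raise ConfigError("admission_mix entries must be probabilities")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ConfigError("admission_mix must sum to 1 within 1e-12")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be positive")
        if self.charlson_rate < 0:
            raise ConfigError("charlson_rate must be non-negative")
        for name in (
            "baseline_infection_prob",
            "daily_event_hazard",
            "discharge_hazard",
            "culture_positive_prob",
            "antibiotic_given_sepsis_prob",
            "source_recorded_prob",
            "spurious_dysfunction_prob",
        ):
            _check_prob(name, getattr(self, name))
        if self.discharge_hazard_ratio_sepsis < 0:
            raise ConfigError("discharge_hazard_ratio_sepsis must be non-negative")
        if self.center_sd < 0:
            raise ConfigError("center_sd must be non-negative")
        if int(self.sepsis_duration_days) < 1:
            raise ConfigError("sepsis_duration_days must be at least 1")
        coeffs = np.atleast_1d(np.asarray(self.sepsis_mortality_log_or, dtype=float))
        if coeffs.size not in (1, 4) or not np.isfinite(coeffs).all():
            raise ConfigError(
                "sepsis_mortality_log_or must be a finite scalar or a "
                "length-4 polynomial coefficient sequence"
            )
        self.daily_sepsis_hazard.validate()
        self.baseline_death_hazard.validate()
        return self

    # -- effect polynomial --------------------------------------------
    def sepsis_effect_at(self, day: np.ndarray | int) -> np.ndarray:
        """True sepsis->death log odds ratio evaluated at hospital day(s)."""
        c = np.atleast_1d(np.asarray(self.sepsis_mortality_log_or, dtype=float))
        t = np.asarray(day, dtype=float)
        if c.size == 1:
            return np.broadcast_to(c[0], t.shape).copy() if t.shape else c[0]
        return c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a configuration from a YAML or JSON file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)
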