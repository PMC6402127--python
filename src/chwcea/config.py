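"""Analysis configuration: valuation policies, utility model, thresholds.

All tunables of the base-case analysis live here so that a run is fully
determined by (input tables, AnalysisConfig). Defaults encode the
base-case study conditions: the 2009 American Samoa minimum wage of
$4.76/h with time-and-a-half over 8 h per episode, a utility decrement
of 0.17 per HbA1c percentage point, 2012 USD as the costing year, and
the six willingness-to-pay thresholds spanning $39 000 (3x local GDP
per capita) to $154 353 (3x US GDP per capita) per QALY.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .exceptions import ConfigurationError
from .taxonomy import DEFAULT_EXCLUSIONS


@dataclass(frozen=True)
class TimeValuationPolicy:
    """How patient time is turned into money.

    Time inside one continuous care episode is paid at ``wage`` up to
    ``overtime_threshold_hours`` and at ``wage * overtime_multiplier``
    beyond it. Outpatient visits are short conventional episodes
    (``minutes_per_outpatient_visit``); an inpatient day occupies
    ``hours_per_inpatient_day`` of patient time and is the only episode
    long enough to attract the overtime premium.
    """

    wage: float = 4.76  # USD per hour, 2009 minimum wage
    overtime_multiplier: float = 1.5
    overtime_threshold_hours: float = 8.0
    minutes_per_outpatient_visit: float = 30.0
    hours_per_inpatient_day: float = 24.0

    def __post_init__(self) -> None:
        if self.wage < 0:
            raise ConfigurationError("wage must be nonnegative")
        if self.overtime_multiplier < 1:
            raise ConfigurationError("overtime_multiplier must be >= 1")
        if self.overtime_threshold_hours <= 0:
            raise ConfigurationError("overtime_threshold_hours must be positive")
        if self.minutes_per_outpatient_visit <= 0 or self.hours_per_inpatient_day <= 0:
            raise ConfigurationError("time conventions must be positive")


@dataclass(frozen=True)
class UtilityModel:
    """Cross-sectional HbA1c-to-utility relationship.

    ``decrement_per_hba1c_point`` is the drop in EQ-5D utility weight
    per additional HbA1c percentage point; the base case uses 0.17
    (US preference weights applied to a Thai T2DM outpatient sample).
    """

    decrement_per_hba1c_point: float = 0.17
    label: str = "base-us-weights"
    horizon_years: float = 1.0

    def __post_init__(self) -> None:
        if self.decrement_per_hba1c_point < 0:
            raise ConfigurationError("utility decrement must be nonnegative")
        if self.horizon_years <= 0:
            raise ConfigurationError("horizon must be positive")


@dataclass(frozen=True)
class EffectEstimate:
    """HbA1c reduction (positive = improvement), optionally with a CI."""

    hba1c_reduction: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.hba1c_reduction <= self.ci_high):
                raise ConfigurationError(
                    "confidence bounds must bracket the point estimate"
                )


#: Willingness-to-pay thresholds (USD per QALY gained).
DEFAULT_THRESHOLDS: dict[str, float] = {
    "local_3x_gdp": 39_000.0,
    "us_conventional_50k": 50_000.0,
    "study_derived_low": 66_351.0,
    "us_2x_gdp": 102_902.0,
    "study_derived_high": 111_134.0,
    "us_3x_gdp": 154_353.0,
}


@dataclass(frozen=True)
class ThresholdSet:
    """Labelled willingness-to-pay thresholds, all strictly positive."""

    entries: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("threshold set must not be empty")
        bad = {k: v for k, v in self.entries.items() if not v > 0}
        if bad:
            raise ConfigurationError(f"thresholds must be positive: {bad}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything tunable about one analysis run.

    ``hba1c_reduction`` overrides the arm difference computed from the
    patient table; the base case consumes the trial's externally
    estimated, covariate-adjusted effect this way. ``medical_indirect_*``
    overrides replace the package's own per-episode valuation of
    medical time with externally calibrated aggregates.
    """

    time_policy: TimeValuationPolicy = field(default_factory=TimeValuationPolicy)
    utility_model: UtilityModel = field(default_factory=UtilityModel)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    step_down_order: tuple[str, ...] | None = None
    exclude_categories: tuple[str, ...] = DEFAULT_EXCLUSIONS
    base_year: int = 2012
    deflator: dict[int, float] | None = None  # None = identity (all 2012 USD)
    person_years: dict[str, float] | None = None  # None = derive from patients
    hba1c_reduction: float | None = None
    intervention_minutes_per_patient: float = 0.0
    medical_indirect_cost_override: float | None = None
    medical_indirect_hours_override: float | None = None
    gdp_per_capita_local: float = 13_000.0
    capacity_rule: str = "busiest_month"  # or "annual_average"

    def __post_init__(self) -> None:
        if self.capacity_rule not in ("busiest_month", "annual_average"):
            raise ConfigurationError(
                "capacity_rule must be 'busiest_month' or 'annual_average'"
            )
        if self.intervention_minutes_per_patient < 0:
            raise ConfigurationError("intervention minutes must be nonnegative")
        if self.person_years is not None:
            if set(self.person_years) != {"chw", "control"}:
                raise ConfigurationError(
                    "person_years must map exactly the arms 'chw' and 'control'"
                )
            if any(v <= 0 for v in self.person_years.values()):
                raise ConfigurationError("person-years must be positive")

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = dict(self.thresholds.entries)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        try:
            if "time_policy" in d and not isinstance(
                d["time_policy"], TimeValuationPolicy
            ):
                d["time_policy"] = TimeValuationPolicy(**d["time_policy"])
            if "utility_model" in d and not isinstance(
                d["utility_model"], UtilityModel
            ):
                d["utility_model"] = UtilityModel(**d["utility_model"])
            if "thresholds" in d and not isinstance(d["thresholds"], ThresholdSet):
                d["thresholds"] = ThresholdSet(dict(d["thresholds"]))
            if d.get("step_down_order") is not None:
                d["step_down_order"] = tuple(d["step_down_order"])
            if d.get("exclude_categories") is not None:
                d["exclude_categories"] = tuple(d["exclude_categories"])
            if d.get("deflator") is not None:
                d["deflator"] = {int(k): float(v) for k, v in d["deflator"].items()}
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(f"bad config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def replace(self, **changes) -> "AnalysisConfig":
        return replace(self, **changes)

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
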