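"""Synthetic cluster-randomized trial data.

Generates the four input tables the analysis consumes — a patient
cohort, encounter streams, a hospital finance ledger, and an
intervention program ledger — with the statistical structure the
pipeline assumes: cluster-level treatment assignment, a fixed additive
treatment effect on the 1-year HbA1c change, Poisson encounter counts
whose intervention-arm post-period rates are shifted by known
per-person-year amounts, and a finance ledger constructed by inverting
the step-down costing engine from chosen unit costs (so the engine
recovers them exactly).

Defaults emulate the study conditions: 104 intervention / 164 control
participants, baseline HbA1c 9.8 ± 2.3%, a −0.53-point treatment
effect, 91% retention, and follow-up denominators of 100 and 163
person-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .costing import DRIVER_PREFIX, step_down_allocate
from .exceptions import ConfigurationError
from .taxonomy import DEFAULT_TAXONOMY, ServiceCategory, validate_categories

HBA1C_RANGE = (3.0, 20.0)

PATIENT_COLUMNS = [
    "patient_id",
    "cluster_id",
    "arm",
    "age",
    "sex",
    "hba1c_baseline",
    "hba1c_followup",
    "retained",
]

ENCOUNTER_COLUMNS = ["patient_id", "period", "category", "quantity"]


@dataclass(frozen=True)
class CohortParams:
    """Cohort-generator parameters; defaults are the study conditions."""

    n_chw: int = 104
    n_control: int = 164
    n_clusters: int = 10
    hba1c_baseline_mean: float = 9.8
    hba1c_baseline_sd: float = 2.3
    treatment_effect: float = -0.53  # HbA1c points; negative = reduction
    secular_drift: float = 0.0  # arm-independent mean change
    followup_noise_sd: float = 1.5  # within-person 1-year variability
    cluster_sd: float = 0.3  # between-village baseline spread
    retention: float = 0.91
    person_years_chw: float = 100.0
    person_years_control: float = 163.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chw, self.n_control, self.n_clusters) < 1:
            raise ConfigurationError("counts must be at least 1")
        if self.hba1c_baseline_sd < 0 or self.followup_noise_sd < 0 or self.cluster_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        if not (0 < self.retention <= 1):
            raise ConfigurationError("retention must be in (0, 1]")
        if self.person_years_chw > self.n_chw or self.person_years_control > self.n_control:
            raise ConfigurationError("person-years cannot exceed arm size")
        if min(self.person_years_chw, self.person_years_control) <= 0:
            raise ConfigurationError("person-years must be positive")

    @property
    def person_years(self) -> dict[str, float]:
        return {"chw": self.person_years_chw, "control": self.person_years_control}


def _truncated_normal(rng, mean, sd, low, high, size):
    if np.all(sd == 0):
        return np.broadcast_to(np.clip(mean, low, high), size).astype(float).copy()
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Cluster-randomized cohort with baseline and follow-up HbA1c.

    Whole clusters are assigned to one arm (cluster counts split in
    proportion to arm sizes, at least one per arm); a village-level
    random shift of SD ``cluster_sd`` induces within-cluster HbA1c
    correlation. Follow-up HbA1c is baseline plus secular drift, the
    treatment effect for the intervention arm, and independent noise;
    it is missing exactly for patients lost to follow-up.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_chw + params.n_control

    n_chw_clusters = int(round(params.n_clusters * params.n_chw / n))
    n_chw_clusters = min(max(n_chw_clusters, 1), params.n_clusters - 1) \
        if params.n_clusters > 1 else 1
    arm_of_cluster = ["chw"] * n_chw_clusters + ["control"] * (
        params.n_clusters - n_chw_clusters
    )

    chw_clusters = [i for i, a in enumerate(arm_of_cluster) if a == "chw"]
    ctl_clusters = [i for i, a in enumerate(arm_of_cluster) if a == "control"]
    if not ctl_clusters:  # single-cluster edge case
        ctl_clusters = chw_clusters

    arms = np.array(["chw"] * params.n_chw + ["control"] * params.n_control)
    cluster_ids = np.empty(n, dtype=int)
    cluster_ids[: params.n_chw] = np.array(chw_clusters)[
        np.arange(params.n_chw) % len(chw_clusters)
    ]
    cluster_ids[params.n_chw :] = np.array(ctl_clusters)[
        np.arange(params.n_control) % len(ctl_clusters)
    ]

    cluster_shift = rng.normal(0.0, params.cluster_sd, size=params.n_clusters)
    lo, hi = HBA1C_RANGE
    baseline = _truncated_normal(
        rng,
        params.hba1c_baseline_mean + cluster_shift[cluster_ids],
        params.hba1c_baseline_sd if params.hba1c_baseline_sd > 0 else 0.0,
        lo,
        hi,
        n,
    )
    noise = (
        rng.normal(0.0, params.followup_noise_sd, size=n)
        if params.followup_noise_sd > 0
        else np.zeros(n)
    )
    effect = np.where(arms == "chw", params.treatment_effect, 0.0)
    followup = np.clip(baseline + params.secular_drift + effect + noise, lo, hi)

    retained = rng.random(n) < params.retention
    followup = np.where(retained, followup, np.nan)

    age = np.clip(rng.normal(55.0, 13.0, size=n), 18, 95).round(0)
    sex = np.where(rng.random(n) < 0.63, "female", "male")

    return pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(n)],
            "cluster_id": [f"c{c:02d}" for c in cluster_ids],
            "arm": arms,
            "age": age,
            "sex": sex,
            "hba1c_baseline": baseline,
            "hba1c_followup": followup,
            "retained": retained,
        },
        columns=PATIENT_COLUMNS,
    )


def observed_hba1c_reduction(patients: pd.DataFrame) -> float:
    """Unadjusted arm difference in mean 1-year HbA1c change.

    Positive = the intervention arm improved more. Computed among
    patients with a follow-up measurement.
    """
    change = patients["hba1c_followup"] - patients["hba1c_baseline"]
    by_arm = change.groupby(patients["arm"]).mean()
    return float(by_arm["control"] - by_arm["chw"])


# ---------------------------------------------------------------------------
# Encounters


@dataclass(frozen=True)
class UtilizationShift:
    """Ground-truth DiD injected into one category (units per patient-year)."""

    category: str
    did_target: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.did_target):
            raise ConfigurationError("did_target must be finite")


#: Per-person-year encounter rates for a high-comorbidity T2DM cohort.
DEFAULT_BASE_RATES: dict[str, float] = {
    "ed": 1.5,
    "ambulatory": 6.0,
    "ward_medical": 0.5,
    "ward_surgical": 0.3,
    "icu": 0.05,
    "surgery": 0.2,
}

#: Default injected shifts (intervention-arm post-period rate changes).
DEFAULT_SHIFTS: tuple[UtilizationShift, ...] = (
    UtilizationShift("ed", -0.61),
    UtilizationShift("ambulatory", -0.18),
    UtilizationShift("ward_medical", -0.12),
    UtilizationShift("ward_surgical", -0.08),
    UtilizationShift("icu", 0.06),
    UtilizationShift("surgery", -0.10),
)


def generate_encounters(
    patients: pd.DataFrame,
    base_rates: dict[str, float] | None = None,
    shifts: tuple[UtilizationShift, ...] | list[UtilizationShift] | None = None,
    seed: int = 0,
    include_intervention: bool = True,
) -> pd.DataFrame:
    """Poisson encounter streams with known intervention-arm rate shifts.

    Every patient-period count for category ``c`` is Poisson with the
    base rate, except the intervention arm's post period, whose rate is
    ``base + shift`` — so the population DiD per person-year equals the
    injected target in expectation. Intervention participation is one
    post-period record per intervention-arm patient. Zero counts are
    not materialized.
    """
    base_rates = dict(DEFAULT_BASE_RATES if base_rates is None else base_rates)
    shifts = tuple(DEFAULT_SHIFTS if shifts is None else shifts)
    validate_categories(base_rates)
    missing = [s.category for s in shifts if s.category not in base_rates]
    if missing:
        raise ConfigurationError(
            f"shifts target categories with no base rate: {missing}"
        )
    shift_by_cat = {s.category: s.did_target for s in shifts}
    for cat, rate in base_rates.items():
        if rate < 0:
            raise ConfigurationError(f"negative base rate for {cat!r}")
        if rate + shift_by_cat.get(cat, 0.0) < 0:
            raise ConfigurationError(
                f"shift {shift_by_cat[cat]} drives the post-period rate of "
                f"{cat!r} below zero (base {rate})"
            )

    rng = np.random.default_rng(seed)
    is_chw = (patients["arm"] == "chw").to_numpy()
    n = len(patients)
    frames = []
    for cat in sorted(base_rates):
        rate = base_rates[cat]
        for period in ("pre", "post"):
            lam = np.full(n, rate)
            if period == "post":
                lam[is_chw] = rate + shift_by_cat.get(cat, 0.0)
            counts = rng.poisson(lam)
            nz = counts > 0
            if nz.any():
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": patients.loc[nz, "patient_id"].to_numpy(),
                            "period": period,
                            "category": cat,
                            "quantity": counts[nz].astype(float),
                        }
                    )
                )
    if include_intervention and is_chw.any():
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patients.loc[is_chw, "patient_id"].to_numpy(),
                    "period": "post",
                    "category": "intervention",
                    "quantity": 1.0,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=ENCOUNTER_COLUMNS)
    return pd.concat(frames, ignore_index=True)[ENCOUNTER_COLUMNS]


# ---------------------------------------------------------------------------
# Finance ledger


@dataclass(frozen=True)
class ActivityCenterSpec:
    name: str
    category: str
    unit_cost: float
    volume: float
    drivers: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OverheadCenterSpec:
    name: str
    driver: str
    cost: float
    drivers: dict[str, float] = field(default_factory=dict)


def ledger_from_unit_costs(
    activities: list[ActivityCenterSpec] | tuple[ActivityCenterSpec, ...],
    overheads: list[OverheadCenterSpec] | tuple[OverheadCenterSpec, ...],
    order: tuple[str, ...] | None = None,
    year: int = 2012,
) -> pd.DataFrame:
    """Construct a finance ledger whose costing output is known exactly.

    For each activity center the target total cost is
    ``unit_cost * volume``; the step-down allocation implied by the
    drivers is computed with the real engine and subtracted to obtain
    the direct cost, so running the engine forward recovers the chosen
    unit costs to machine precision. Raises if any implied direct cost
    would be negative (overhead too large for the chosen targets).
    """
    if not activities:
        raise ConfigurationError("at least one activity center required")
    driver_names = sorted(
        {o.driver for o in overheads}
        | {d for a in activities for d in a.drivers}
        | {d for o in overheads for d in o.drivers}
    )
    for o in overheads:
        missing = [
            a.name for a in activities if o.driver not in a.drivers
        ]
        if missing:
            raise ConfigurationError(
                f"activity centers {missing} lack driver {o.driver!r} "
                f"required by overhead center {o.name!r}"
            )

    def row(name, kind, direct, volume, category, driver, drivers):
        r = {
            "center": name,
            "kind": kind,
            "direct_cost": direct,
            "year": year,
            "volume": volume,
            "category": category,
            "driver": driver,
        }
        for d in driver_names:
            r[DRIVER_PREFIX + d] = drivers.get(d, 0.0)
        return r

    rows = [
        row(o.name, "overhead", o.cost, np.nan, "", o.driver, o.drivers)
        for o in overheads
    ]
    # provisional zero direct costs; allocation is independent of them
    rows += [
        row(a.name, "activity", 0.0, a.volume, a.category, "", a.drivers)
        for a in activities
    ]
    ledger = pd.DataFrame(rows)
    alloc = (
        step_down_allocate(ledger, order=order)
        if overheads
        else {a.name: 0.0 for a in activities}
    )
    for a in activities:
        direct = a.unit_cost * a.volume - alloc[a.name]
        if direct < 0:
            raise ConfigurationError(
                f"allocated overhead ({alloc[a.name]:.2f}) exceeds target total "
                f"cost for activity center {a.name!r}"
            )
        ledger.loc[ledger["center"] == a.name, "direct_cost"] = direct
    return ledger


@dataclass(frozen=True)
class FinanceLedgerSpec:
    """Randomized-ledger parameters; defaults mirror a small island hospital."""

    n_ambulatory_clinics: int = 7
    unit_cost_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ed": (100.0, 180.0),
            "ambulatory": (150.0, 280.0),
            "ward_medical": (250.0, 450.0),
            "ward_surgical": (250.0, 500.0),
            "icu": (1000.0, 2000.0),
            "surgery": (100.0, 200.0),
        }
    )
    overhead_fraction: float = 0.02  # overhead pool as share of total cost

    def __post_init__(self) -> None:
        if self.n_ambulatory_clinics < 2:
            raise ConfigurationError("need at least 2 ambulatory clinics")
        if not (0 < self.overhead_fraction < 1):
            raise ConfigurationError("overhead_fraction must be in (0, 1)")


AMBULATORY_CLINIC_NAMES = (
    "internal_medicine_clinic",
    "primary_care_clinic",
    "community_health_center",
    "ophthalmology_clinic",
    "surgical_clinic",
    "mental_health_clinic",
    "ent_clinic",
)


def generate_finance_ledger(
    spec: FinanceLedgerSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Random hospital finance ledger with internally consistent costing.

    Contains an ED, the configured number of ambulatory clinics, three
    wards (medical, surgical, ICU), a surgical facility, and four
    overhead centers (administration/staff, plant operations/floor
    space, patient services/patient count, clinical support/
    inpatient-equivalent days). Unit costs are drawn from the
    configured ranges and the ledger is constructed so the costing
    engine reproduces them exactly.
    """
    spec = FinanceLedgerSpec() if spec is None else spec
    rng = np.random.default_rng(seed)

    def u(cat):
        lo, hi = spec.unit_cost_ranges[cat]
        return float(rng.uniform(lo, hi))

    clinic_names = [
        AMBULATORY_CLINIC_NAMES[i % len(AMBULATORY_CLINIC_NAMES)]
        + ("" if i < len(AMBULATORY_CLINIC_NAMES) else f"_{i}")
        for i in range(spec.n_ambulatory_clinics)
    ]
    activities: list[ActivityCenterSpec] = []

    def drivers(staff, space, patients, ied):
        return {
            "staff": staff,
            "floor_space": space,
            "patients": patients,
            "inpatient_equiv_days": ied,
        }

    for name in clinic_names:
        vol = float(rng.integers(800, 9000))
        activities.append(
            ActivityCenterSpec(
                name,
                "ambulatory",
                u("ambulatory"),
                vol,
                drivers(rng.integers(4, 16), rng.integers(80, 400), vol, vol / 3.0),
            )
        )
    ed_vol = float(rng.integers(8000, 16000))
    activities.append(
        ActivityCenterSpec(
            "emergency_department",
            "ed",
            u("ed"),
            ed_vol,
            drivers(30, 600, ed_vol, ed_vol / 3.0),
        )
    )
    for name, cat, vol_range, staff in [
        ("medical_ward", "ward_medical", (2500, 4000), 28),
        ("surgical_ward", "ward_surgical", (1500, 2500), 22),
        ("intensive_care_unit", "icu", (350, 700), 16),
    ]:
        vol = float(rng.integers(*vol_range))
        activities.append(
            ActivityCenterSpec(
                name, cat, u(cat), vol, drivers(staff, rng.integers(300, 900), vol / 4.0, vol)
            )
        )
    surg_vol = float(rng.integers(500, 1200))
    activities.append(
        ActivityCenterSpec(
            "surgical_facility",
            "surgery",
            u("surgery"),
            surg_vol,
            drivers(20, 500, surg_vol, surg_vol),
        )
    )

    total_target = sum(a.unit_cost * a.volume for a in activities)
    pool = spec.overhead_fraction * total_target
    overheads = [
        OverheadCenterSpec("administration", "staff", 0.4 * pool),
        OverheadCenterSpec(
            "plant_operations", "floor_space", 0.2 * pool, {"staff": 6.0}
        ),
        OverheadCenterSpec(
            "patient_services", "patients", 0.2 * pool, {"staff": 5.0, "floor_space": 150.0}
        ),
        OverheadCenterSpec(
            "clinical_support",
            "inpatient_equiv_days",
            0.2 * pool,
            {"staff": 10.0, "floor_space": 400.0, "patients": 0.0},
        ),
    ]
    order = tuple(o.name for o in overheads)
    return ledger_from_unit_costs(activities, overheads, order=order)


def generate_intervention_ledger(
    participants: int = 104, seed: int = 0
) -> "InterventionLedger":
    """Plausible home-visit program ledger for ``participants`` patients."""
    from .costing import InterventionLedger

    rng = np.random.default_rng(seed)
    monthly = rng.integers(60, 130, size=12).astype(float)
    quarters = [f"Q{i + 1}" for i in range(4)]
    visits_q = [float(monthly[3 * i : 3 * i + 3].sum()) for i in range(4)]
    consumables_q = [float(rng.uniform(1200, 2000)) for _ in range(4)]
    return InterventionLedger(
        consumables_by_quarter=tuple(zip(quarters, consumables_q)),
        visits_by_quarter=tuple(zip(quarters, visits_q)),
        startup_capital=float(rng.uniform(60_000, 100_000)),
        staff_salary_share=float(rng.uniform(50_000, 75_000)),
        space_opportunity_cost=float(rng.uniform(6_000, 9_000)),
        visits_by_month=tuple(
            (f"M{i + 1:02d}", float(v)) for i, v in enumerate(monthly)
        ),
        participants=participants,
    )
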