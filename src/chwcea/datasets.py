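"""Deterministic study-calibrated dataset.

:func:`study_fixture` builds, with no randomness, a complete input
bundle (patients, encounters, finance ledger, intervention ledger,
config) calibrated so that the pipeline reproduces the published
per-patient results of the American Samoa community-health-worker
diabetes trial: a −0.53-point HbA1c effect, per-person-year
utilization DiDs of +1.00 (intervention participation), −0.61 (ED
visits), −0.18 (ambulatory visits), −0.14 (inpatient days, the net of
ward-level changes including +0.06 ICU days), −0.10 (surgical
procedures), an intervention direct cost of $677.43 per participant
(staffing 439.18, equipment 124.24, space 52.94, consumables 61.07),
and a net incremental cost of $594.27 per patient per year.

Calibration conventions
-----------------------
Unit costs not published directly are back-computed as ratios of
published cost and utilization aggregates (e.g. ED: 83.77 / 0.61 =
$137.33 per visit); ward-level inpatient unit costs are synthetic
values constrained to the two published facts (+0.06 ICU days, net
hospitalization cost DiD +$19.29). The medical-indirect row is
carried as a calibrated aggregate (hours −3.74, cost −15.1387, the
residual of the published total against the other full-precision
components) because the published value is not reproducible from any
stated valuation rule applied to the rounded utilization aggregates;
the package's own per-episode valuation is available via
:func:`chwcea.timevalue.medical_indirect_did` and the difference is
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .costing import InterventionLedger
from .exceptions import DataError
from .simulate import (
    ENCOUNTER_COLUMNS,
    PATIENT_COLUMNS,
    ActivityCenterSpec,
    OverheadCenterSpec,
    ledger_from_unit_costs,
)

# Published per-person-year utilization aggregates (intervention arm
# relative to control).
FIXTURE_UTILIZATION_DID = {
    "intervention": 1.00,
    "ed": -0.61,
    "ambulatory": -0.18,
    "ward_medical": -0.12,  # calibrated ward split; net days −0.14
    "ward_surgical": -0.08,
    "icu": 0.06,  # published: slight ICU increase
    "surgery": -0.10,
}

# Unit costs: back-computed ratios of published aggregates, and
# calibrated ward-level rates.
FIXTURE_UNIT_COSTS = {
    "ed": 83.77 / 0.61,  # 137.33 per visit
    "ambulatory": 38.38 / 0.18,  # 213.22 per visit
    "ward_medical": 350.0,  # synthetic calibration
    "ward_surgical": 358.875,  # synthetic: closes +19.29 with ICU at 1500
    "icu": 1500.0,  # synthetic calibration
    "surgery": 12.92 / 0.10,  # 129.20 per procedure
    "maternity_ward": 400.0,  # excluded from the analysis
    "obgyn_clinic": 200.0,  # excluded from the analysis
}

#: Medical-indirect patient-time row, calibrated (see module docstring).
FIXTURE_MEDICAL_INDIRECT_HOURS = -3.74
FIXTURE_MEDICAL_INDIRECT_COST = -15.138667

#: Mean patient minutes spent in intervention home visits.
FIXTURE_INTERVENTION_MINUTES = 602.0

FIXTURE_PERSON_YEARS = {"chw": 100.0, "control": 163.0}

STEP_DOWN_ORDER = (
    "administration",
    "plant_operations",
    "patient_services",
    "clinical_support",
)


@dataclass(frozen=True)
class FixtureBundle:
    """All pipeline inputs for the calibrated study dataset."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    finance_ledger: pd.DataFrame
    intervention_ledger: InterventionLedger
    config: AnalysisConfig


def _fixture_patients() -> pd.DataFrame:
    """268 patients: 104 intervention (HbA1c 9.6 → 9.07), 164 control (10.0, flat).

    The arm difference in mean HbA1c change is exactly −0.53; all
    patients are retained (follow-up person-years are supplied
    separately as the published 100 / 163 denominators).
    """
    rows = []
    for i in range(104):
        rows.append(
            {
                "patient_id": f"p{i:04d}",
                "cluster_id": f"c{i % 4:02d}",
                "arm": "chw",
                "age": 56.0,
                "sex": "female" if i % 5 < 3 else "male",
                "hba1c_baseline": 9.6,
                "hba1c_followup": 9.6 - 0.53,
                "retained": True,
            }
        )
    for i in range(164):
        rows.append(
            {
                "patient_id": f"p{104 + i:04d}",
                "cluster_id": f"c{4 + i % 4:02d}",
                "arm": "control",
                "age": 54.0,
                "sex": "female" if i % 3 < 2 else "male",
                "hba1c_baseline": 10.0,
                "hba1c_followup": 10.0,
                "retained": True,
            }
        )
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def _fixture_encounters() -> pd.DataFrame:
    """Aggregate encounter rows encoding the published DiDs exactly.

    Published values are rounded per-person-year aggregates, not raw
    event streams, so the fixture encodes each category's arm-level
    total directly: a reduction of ``x`` per person-year over 100
    intervention person-years appears as a pre-period quantity of
    ``100 x`` (and an increase as a post-period quantity). Control-arm
    utilization is present but balanced (pre = post), contributing
    zero to every DiD. Maternity / Ob-Gyn rows exist and are excluded
    by the config.
    """
    chw0, chw1, ctl0 = "p0000", "p0001", "p0104"
    py = FIXTURE_PERSON_YEARS["chw"]
    rows = []

    def add(pid, period, category, quantity):
        rows.append(
            {"patient_id": pid, "period": period, "category": category,
             "quantity": float(quantity)}
        )

    for category, did in FIXTURE_UTILIZATION_DID.items():
        if did >= 0:
            add(chw0, "post", category, did * py)
        else:
            add(chw0, "pre", category, -did * py)

    # balanced background utilization (cancels in every DiD)
    for category, pre, post in [
        ("ed", 180.0, 180.0),
        ("ambulatory", 900.0, 900.0),
        ("ward_medical", 60.0, 60.0),
    ]:
        add(chw1, "pre", category, pre * 100 / 163)
        add(chw1, "post", category, post * 100 / 163)
        add(ctl0, "pre", category, pre)
        add(ctl0, "post", category, post)

    # pregnancy-related care, excluded from the diabetes analysis
    add(chw0, "pre", "maternity_ward", 3.0)
    add(chw0, "post", "maternity_ward", 5.0)
    add(ctl0, "post", "obgyn_clinic", 4.0)

    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


def _fixture_finance_ledger() -> pd.DataFrame:
    """Hospital ledger whose step-down costing yields the fixture unit costs.

    Seven ambulatory clinics share one pooled unit cost (their
    volume-weighted mean is then that same cost); the ED, three wards,
    the surgical facility, and the excluded maternity/Ob-Gyn centers
    complete the activity side. Four overhead centers use the four
    canonical drivers.
    """
    def drv(staff, space, patients, ied):
        return {
            "staff": float(staff),
            "floor_space": float(space),
            "patients": float(patients),
            "inpatient_equiv_days": float(ied),
        }

    amb = FIXTURE_UNIT_COSTS["ambulatory"]
    clinics = [
        ("internal_medicine_clinic", 6000.0, 12, 250),
        ("primary_care_clinic", 8000.0, 14, 300),
        ("community_health_center", 5000.0, 10, 220),
        ("ophthalmology_clinic", 1500.0, 5, 120),
        ("surgical_clinic", 1200.0, 5, 110),
        ("mental_health_clinic", 900.0, 4, 100),
        ("ent_clinic", 800.0, 4, 90),
    ]
    activities = [
        ActivityCenterSpec(
            name, "ambulatory", amb, vol, drv(staff, space, vol, vol / 3.0)
        )
        for name, vol, staff, space in clinics
    ]
    activities += [
        ActivityCenterSpec(
            "emergency_department", "ed", FIXTURE_UNIT_COSTS["ed"], 12000.0,
            drv(30, 600, 12000, 4000),
        ),
        ActivityCenterSpec(
            "medical_ward", "ward_medical", FIXTURE_UNIT_COSTS["ward_medical"],
            3000.0, drv(28, 700, 750, 3000),
        ),
        ActivityCenterSpec(
            "surgical_ward", "ward_surgical", FIXTURE_UNIT_COSTS["ward_surgical"],
            2000.0, drv(22, 600, 500, 2000),
        ),
        ActivityCenterSpec(
            "intensive_care_unit", "icu", FIXTURE_UNIT_COSTS["icu"], 500.0,
            drv(16, 400, 125, 500),
        ),
        ActivityCenterSpec(
            "surgical_facility", "surgery", FIXTURE_UNIT_COSTS["surgery"], 800.0,
            drv(20, 500, 800, 800),
        ),
        ActivityCenterSpec(
            "maternity_ward", "maternity_ward",
            FIXTURE_UNIT_COSTS["maternity_ward"], 1200.0,
            drv(18, 500, 300, 1200),
        ),
        ActivityCenterSpec(
            "obgyn_clinic", "obgyn_clinic", FIXTURE_UNIT_COSTS["obgyn_clinic"],
            1500.0, drv(6, 150, 1500, 500),
        ),
    ]
    overheads = [
        OverheadCenterSpec("administration", "staff", 50_000.0),
        OverheadCenterSpec("plant_operations", "floor_space", 30_000.0, {"staff": 6.0}),
        OverheadCenterSpec(
            "patient_services", "patients", 40_000.0,
            {"staff": 5.0, "floor_space": 150.0},
        ),
        OverheadCenterSpec(
            "clinical_support", "inpatient_equiv_days", 60_000.0,
            {"staff": 10.0, "floor_space": 400.0, "patients": 0.0},
        ),
    ]
    return ledger_from_unit_costs(activities, overheads, order=STEP_DOWN_ORDER)


def _fixture_intervention_ledger() -> InterventionLedger:
    """Program ledger inverted from the published cost components.

    1040 home visits over the year (mean 10 per participant), busiest
    month 120 visits. Annual fixed amounts are chosen so the
    busiest-month rule returns the published staffing / equipment /
    space components; quarterly consumables sum to 104 x $61.07.
    """
    months = [70, 80, 110, 75, 85, 100, 90, 80, 90, 70, 70, 120]
    # annual = component * 12 * busiest / mean_visits = component * 144
    return InterventionLedger(
        consumables_by_quarter=(
            ("Q1", 1500.0), ("Q2", 1600.0), ("Q3", 1700.0), ("Q4", 1551.28),
        ),
        visits_by_quarter=(("Q1", 260.0), ("Q2", 260.0), ("Q3", 260.0), ("Q4", 260.0)),
        startup_capital=124.24 * 144 * 5,  # 89 452.80, depreciated over 5 y
        staff_salary_share=439.18 * 144,  # 63 241.92 / y
        space_opportunity_cost=52.94 * 144,  # 7 623.36 / y
        visits_by_month=tuple((f"M{i + 1:02d}", float(v)) for i, v in enumerate(months)),
        participants=104,
    )


def fixture_config() -> AnalysisConfig:
    """Base-case configuration for the calibrated dataset."""
    return AnalysisConfig(
        step_down_order=STEP_DOWN_ORDER,
        person_years=dict(FIXTURE_PERSON_YEARS),
        intervention_minutes_per_patient=FIXTURE_INTERVENTION_MINUTES,
        medical_indirect_cost_override=FIXTURE_MEDICAL_INDIRECT_COST,
        medical_indirect_hours_override=FIXTURE_MEDICAL_INDIRECT_HOURS,
    )


def study_fixture() -> FixtureBundle:
    """Build the complete deterministic input bundle (no RNG anywhere)."""
    bundle = FixtureBundle(
        patients=_fixture_patients(),
        encounters=_fixture_encounters(),
        finance_ledger=_fixture_finance_ledger(),
        intervention_ledger=_fixture_intervention_ledger(),
        config=fixture_config(),
    )
    if len(bundle.patients) != 268:
        raise DataError("fixture cohort must have 268 patients")
    return bundle
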