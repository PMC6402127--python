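"""Utilization difference-in-differences and its conversion to costs.

For each service category the utilization DiD per patient per year is

    [sum_chw(post) - sum_chw(pre)] / py_chw
        - [sum_ctrl(post) - sum_ctrl(pre)] / py_ctrl

where the pre period covers the 12 months before enrollment, the post
period the 12 months after, and ``py`` are follow-up person-years per
arm. Multiplying each utilization DiD by the category's unit cost
gives the cost DiD; adding the intervention direct row (participation
DiD times program cost per participant) and the two indirect
patient-time rows yields the total incremental cost per patient per
year — the numerator of the ICER.

All computation is at full precision; rounding happens only in
display code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .taxonomy import (
    DEFAULT_TAXONOMY,
    GROUP_LABELS,
    GROUP_ORDER,
    Group,
    ServiceCategory,
    group_of,
    validate_categories,
)

ARMS = ("chw", "control")
PERIODS = ("pre", "post")


def _validate_encounters(encounters: pd.DataFrame, patients: pd.DataFrame) -> None:
    for col in ("patient_id", "period", "category", "quantity"):
        if col not in encounters.columns:
            raise DataError(f"encounters table missing column {col!r}")
    bad_period = set(encounters["period"]) - set(PERIODS)
    if bad_period:
        raise DataError(f"unknown periods {sorted(bad_period)}; expected {PERIODS}")
    if (encounters["quantity"] < 0).any():
        raise DataError("encounter quantities must be nonnegative")
    unknown_patients = set(encounters["patient_id"]) - set(patients["patient_id"])
    if unknown_patients:
        raise DataError(
            f"encounters reference unknown patients: {sorted(unknown_patients)[:5]}"
        )
    bad_arm = set(patients["arm"]) - set(ARMS)
    if bad_arm:
        raise DataError(f"unknown arms {sorted(bad_arm)}; expected {ARMS}")


def utilization_did(
    encounters: pd.DataFrame,
    patients: pd.DataFrame,
    person_years: dict[str, float],
    taxonomy: dict[str, ServiceCategory] | None = None,
    exclude: tuple[str, ...] = (),
) -> pd.Series:
    """Per-category utilization DiD, units per patient per year.

    ``exclude`` drops categories (e.g. maternity ward, Ob-Gyn clinic)
    before any aggregation. Categories with no encounters at all are
    omitted; categories observed in only one arm/period contribute
    with the missing cells as zero.
    """
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    _validate_encounters(encounters, patients)
    validate_categories(encounters["category"].unique(), taxonomy)
    for arm in ARMS:
        if arm not in person_years or person_years[arm] <= 0:
            raise DataError(f"person-years must be positive for arm {arm!r}")

    enc = encounters[~encounters["category"].isin(exclude)]
    if enc.empty:
        return pd.Series(dtype=float, name="utilization_did")
    merged = enc.merge(
        patients[["patient_id", "arm"]], on="patient_id", how="left", validate="m:1"
    )
    totals = (
        merged.groupby(["category", "arm", "period"], sort=True)["quantity"]
        .sum()
        .unstack(["arm", "period"], fill_value=0.0)
    )
    # guarantee all four cells exist
    for arm in ARMS:
        for period in PERIODS:
            if (arm, period) not in totals.columns:
                totals[(arm, period)] = 0.0

    did = (totals[("chw", "post")] - totals[("chw", "pre")]) / person_years["chw"] - (
        totals[("control", "post")] - totals[("control", "pre")]
    ) / person_years["control"]
    did.name = "utilization_did"
    return did.sort_index()


def person_years_from_patients(
    patients: pd.DataFrame, dropout_fraction: float = 0.5
) -> dict[str, float]:
    """Approximate follow-up person-years per arm from retention flags.

    Retained patients contribute a full year; patients lost to
    follow-up contribute ``dropout_fraction`` of a year (dropout times
    are not recorded, so mid-year loss is assumed).
    """
    out = {}
    for arm, sub in patients.groupby("arm"):
        retained = sub["retained"].astype(bool)
        out[str(arm)] = float(retained.sum() + dropout_fraction * (~retained).sum())
    return out


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndirectRows:
    """Patient-time rows appended to the cost DiD table.

    Hours are per patient per year (display only); costs enter the
    total. ``intervention`` is time spent in home visits; ``medical``
    is the DiD of time spent in medical care.
    """

    intervention_cost: float
    medical_cost: float
    intervention_hours: float = float("nan")
    medical_hours: float = float("nan")


@dataclass(frozen=True)
class DiDTable:
    """Full incremental-cost table: one row per category plus indirect rows.

    ``detail`` has one row per service category (index = category key)
    with utilization and cost DiDs; ``by_group()`` collapses it to the
    five reporting groups. ``total`` is the sum of all cost rows —
    the incremental cost per patient per year.
    """

    detail: pd.DataFrame  # index category; columns group, utilization_did, cost_did
    indirect: IndirectRows
    person_years: dict[str, float]

    @property
    def total(self) -> float:
        return float(
            self.detail["cost_did"].sum()
            + self.indirect.intervention_cost
            + self.indirect.medical_cost
        )

    def by_group(self) -> pd.DataFrame:
        """Reporting-group table in presentation order."""
        g = (
            self.detail.groupby("group", sort=False)[["utilization_did", "cost_did"]]
            .sum()
            .reindex([grp.value for grp in GROUP_ORDER])
            .dropna(how="all")
        )
        g.index = [GROUP_LABELS[Group(i)] for i in g.index]
        return g

    def to_frame(self) -> pd.DataFrame:
        """Flat table including indirect rows and the total (for CSV/report)."""
        rows = self.detail.reset_index().rename(columns={"index": "category"})
        extra = pd.DataFrame(
            [
                {
                    "category": "intervention_indirect",
                    "group": "indirect",
                    "utilization_did": self.indirect.intervention_hours,
                    "cost_did": self.indirect.intervention_cost,
                },
                {
                    "category": "medical_indirect",
                    "group": "indirect",
                    "utilization_did": self.indirect.medical_hours,
                    "cost_did": self.indirect.medical_cost,
                },
                {
                    "category": "total",
                    "group": "total",
                    "utilization_did": np.nan,
                    "cost_did": self.total,
                },
            ]
        )
        return pd.concat([rows, extra], ignore_index=True)


def cost_did(
    udid: pd.Series,
    unit_cost_table: pd.DataFrame,
    intervention_cost: float,
    indirect: IndirectRows,
    person_years: dict[str, float] | None = None,
    taxonomy: dict[str, ServiceCategory] | None = None,
) -> DiDTable:
    """Convert utilization DiDs to money and assemble the full table.

    Medical categories are valued at their unit cost; the intervention
    participation row is valued at the program's direct cost per
    participant. Cost DiDs are linear in both the utilization DiDs and
    the unit costs, so a category with reduced use and a positive unit
    cost always shows a saving.
    """
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    validate_categories(udid.index, taxonomy)
    rows = {}
    for key, u in udid.items():
        grp = group_of(key, taxonomy)
        if grp is Group.INTERVENTION:
            cost = float(u) * float(intervention_cost)
        else:
            if key not in unit_cost_table.index:
                raise ConfigurationError(
                    f"no unit cost for category {key!r} present in the DiD table"
                )
            cost = float(u) * float(unit_cost_table.loc[key, "unit_cost"])
        rows[key] = {"group": grp.value, "utilization_did": float(u), "cost_did": cost}
    if rows:
        detail = pd.DataFrame.from_dict(rows, orient="index")
    else:
        detail = pd.DataFrame(columns=["group", "utilization_did", "cost_did"])
    detail.index.name = "category"
    return DiDTable(
        detail=detail,
        indirect=indirect,
        person_years=dict(person_years or {}),
    )
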