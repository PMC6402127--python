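"""Indirect (patient-time) cost valuation.

Patient time is valued with a human-capital approach at a policy wage
with an overtime premium: within one continuous care episode, hours up
to the overtime threshold are paid at the flat wage and hours beyond
it at wage times the overtime multiplier. The premium is applied per
episode, never to hours summed across episodes — many short outpatient
visits do not add up to "overtime", but a 24-hour inpatient day does.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

from .config import TimeValuationPolicy
from .exceptions import DataError
from .taxonomy import Group


def value_episode(hours: float, policy: TimeValuationPolicy) -> float:
    """Money value of one continuous episode of ``hours`` patient-hours.

    Piecewise linear, continuous, convex and nondecreasing in hours;
    equals ``wage * hours`` exactly when the episode fits under the
    overtime threshold.
    """
    if hours < 0:
        raise DataError("episode hours must be nonnegative")
    t = policy.overtime_threshold_hours
    base = min(hours, t) * policy.wage
    overtime = max(hours - t, 0.0) * policy.wage * policy.overtime_multiplier
    return base + overtime


def intervention_indirect_cost(
    minutes_per_patient: float, policy: TimeValuationPolicy
) -> float:
    """Value of patient time spent in intervention home visits, per patient.

    Every home visit is a separate episode far below the overtime
    threshold, so the total is flat wage times total hours.
    """
    if minutes_per_patient < 0:
        raise DataError("minutes must be nonnegative")
    return (minutes_per_patient / 60.0) * policy.wage


class MedicalIndirectDiD(NamedTuple):
    hours_did: float
    cost_did: float


def medical_indirect_did(
    udid_by_group: Mapping, policy: TimeValuationPolicy
) -> MedicalIndirectDiD:
    """Patient-time difference-in-differences for medical care.

    ED, ambulatory and surgery contacts each occupy the outpatient
    time convention (default 30 min, flat wage); an inpatient day is
    one continuous episode of the inpatient time convention (default
    24 h, overtime premium applies). Inputs are group-level
    utilization DiDs per patient per year; outputs are the implied
    hours and money DiDs per patient per year.
    """
    def get(group: Group) -> float:
        for key in (group, group.value):
            if key in udid_by_group:
                return float(udid_by_group[key])
        return 0.0

    outpatient_contacts = get(Group.ED) + get(Group.AMBULATORY) + get(Group.SURGERY)
    inpatient_days = get(Group.HOSPITALIZATION)

    visit_hours = policy.minutes_per_outpatient_visit / 60.0
    day_hours = policy.hours_per_inpatient_day

    hours = visit_hours * outpatient_contacts + day_hours * inpatient_days
    cost = (
        value_episode(visit_hours, policy) * outpatient_contacts
        + value_episode(day_hours, policy) * inpatient_days
    )
    return MedicalIndirectDiD(hours_did=hours, cost_did=cost)
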