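"""Service-category taxonomy.

Utilization and costing are tracked at the level of fine-grained
service categories (individual wards, the ED, the pooled ambulatory
clinics, the surgical facility, intervention participation). Each
category belongs to one of five reporting groups — intervention, ED,
ambulatory, hospitalization, surgery — and is measured in a fixed
natural unit (visit, inpatient day, procedure, or participation).

Hospital wards keep distinct keys because their unit costs differ by
an order of magnitude (an ICU day versus a medical-ward day), and the
group-level cost difference must be assembled ward by ward: a small
utilization increase in an expensive ward can dominate a net decrease
in total inpatient days.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .exceptions import ConfigurationError


class Group(str, Enum):
    INTERVENTION = "intervention"
    ED = "ed"
    AMBULATORY = "ambulatory"
    HOSPITALIZATION = "hospitalization"
    SURGERY = "surgery"


class Unit(str, Enum):
    VISIT = "visit"
    INPATIENT_DAY = "inpatient_day"
    PROCEDURE = "procedure"
    PARTICIPATION = "participation"


@dataclass(frozen=True)
class ServiceCategory:
    """One service category: a unique key, its reporting group, its unit."""

    key: str
    group: Group
    unit: Unit


#: Default taxonomy. ``ambulatory`` pools the outpatient clinics
#: (internal medicine, primary care, community health center,
#: ophthalmology, surgical clinic, mental health, ENT); wards are kept
#: separate; ``maternity_ward`` and ``obgyn_clinic`` exist so that
#: pregnancy-related utilization can be represented and then excluded
#: from the diabetes analysis.
DEFAULT_TAXONOMY: dict[str, ServiceCategory] = {
    c.key: c
    for c in [
        ServiceCategory("intervention", Group.INTERVENTION, Unit.PARTICIPATION),
        ServiceCategory("ed", Group.ED, Unit.VISIT),
        ServiceCategory("ambulatory", Group.AMBULATORY, Unit.VISIT),
        ServiceCategory("ward_medical", Group.HOSPITALIZATION, Unit.INPATIENT_DAY),
        ServiceCategory("ward_surgical", Group.HOSPITALIZATION, Unit.INPATIENT_DAY),
        ServiceCategory("icu", Group.HOSPITALIZATION, Unit.INPATIENT_DAY),
        ServiceCategory("surgery", Group.SURGERY, Unit.PROCEDURE),
        ServiceCategory("maternity_ward", Group.HOSPITALIZATION, Unit.INPATIENT_DAY),
        ServiceCategory("obgyn_clinic", Group.AMBULATORY, Unit.VISIT),
    ]
}

#: Categories excluded from the base analysis: changes in maternity /
#: Ob-Gyn utilization are unrelated to glycemic control in an older
#: adult T2DM cohort.
DEFAULT_EXCLUSIONS: tuple[str, ...] = ("maternity_ward", "obgyn_clinic")

GROUP_ORDER: tuple[Group, ...] = (
    Group.INTERVENTION,
    Group.ED,
    Group.AMBULATORY,
    Group.HOSPITALIZATION,
    Group.SURGERY,
)

GROUP_LABELS: dict[Group, str] = {
    Group.INTERVENTION: "Intervention (use)",
    Group.ED: "ED (visits)",
    Group.AMBULATORY: "Ambulatory (visits)",
    Group.HOSPITALIZATION: "Hospitalizations (inpatient days)",
    Group.SURGERY: "Surgery (procedures)",
}


def group_of(key: str, taxonomy: dict[str, ServiceCategory] | None = None) -> Group:
    """Reporting group of a category key; unknown keys raise."""
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    try:
        return taxonomy[key].group
    except KeyError:
        raise ConfigurationError(
            f"unknown service category {key!r}; known: {sorted(taxonomy)}"
        ) from None


def validate_categories(
    keys, taxonomy: dict[str, ServiceCategory] | None = None
) -> None:
    """Raise :class:`ConfigurationError` if any key is outside the taxonomy."""
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    unknown = sorted(set(keys) - set(taxonomy))
    if unknown:
        raise ConfigurationError(
            f"unknown service categories {unknown}; known: {sorted(taxonomy)}"
        )
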