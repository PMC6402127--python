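"""Activity-based micro-costing with step-down overhead allocation.

A facility's finance ledger is a table of cost centers. *Overhead*
centers (administration, plant operations, patient services, clinical
support services) do not produce billable output; their pools are
step-allocated to the remaining centers proportionally to an
allocation driver (staff count for administration, floor space for
plant upkeep and laundry, patient count for patient-service
management, inpatient-equivalent days for clinical support such as the
lab). *Activity* centers (clinics, the ED, wards, the surgical
facility) produce output; their total cost — direct plus allocated
overhead — divided by output volume gives the unit cost per visit,
inpatient day, or procedure.

Step-down allocation is sequential: overhead centers are processed in
a declared order; each pool (direct cost plus anything allocated to it
by earlier pools) is distributed over all not-yet-allocated centers,
and a center never receives anything after its own pool has been
distributed. The result depends (boundedly) on the order;
:func:`allocation_order_report` documents that dependence rather than
hiding it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ComputationError, ConfigurationError, DataError

DRIVER_PREFIX = "driver:"

LEDGER_BASE_COLUMNS = ["center", "kind", "direct_cost", "year", "volume", "category", "driver"]


def _driver_columns(ledger: pd.DataFrame) -> list[str]:
    return [c for c in ledger.columns if c.startswith(DRIVER_PREFIX)]


def validate_ledger(ledger: pd.DataFrame) -> None:
    """Structural checks shared by all costing entry points."""
    missing = [c for c in LEDGER_BASE_COLUMNS if c not in ledger.columns]
    if missing:
        raise DataError(f"finance ledger missing columns: {missing}")
    if ledger["center"].duplicated().any():
        dup = ledger.loc[ledger["center"].duplicated(), "center"].tolist()
        raise DataError(f"duplicate cost centers: {dup}")
    bad_kind = set(ledger["kind"]) - {"overhead", "activity"}
    if bad_kind:
        raise DataError(f"unknown cost-center kinds: {sorted(bad_kind)}")
    if (ledger["direct_cost"] < 0).any():
        raise DataError("direct costs must be nonnegative")
    overhead = ledger[ledger["kind"] == "overhead"]
    for _, row in overhead.iterrows():
        drv = row["driver"]
        if not isinstance(drv, str) or not drv:
            raise DataError(f"overhead center {row['center']!r} has no driver")
        if DRIVER_PREFIX + drv not in ledger.columns:
            raise ConfigurationError(
                f"ledger has no column {DRIVER_PREFIX + drv!r} for overhead "
                f"center {row['center']!r}"
            )
    activity = ledger[ledger["kind"] == "activity"]
    if (activity["volume"] <= 0).any() or activity["volume"].isna().any():
        bad = activity.loc[
            ~(activity["volume"] > 0), "center"
        ].tolist()
        raise DataError(f"activity centers need positive output volume: {bad}")
    if activity["category"].isna().any() or (activity["category"] == "").any():
        bad = activity.loc[
            activity["category"].isna() | (activity["category"] == ""), "center"
        ].tolist()
        raise DataError(f"activity centers need a service category: {bad}")
    drv_cols = _driver_columns(ledger)
    for _, row in overhead.iterrows():
        col = DRIVER_PREFIX + row["driver"]
        vals = activity[col]
        if vals.isna().any() or (vals < 0).any():
            raise ConfigurationError(
                f"every activity center needs a nonnegative {col!r} value "
                f"(driver of overhead center {row['center']!r})"
            )
    if drv_cols and (ledger[drv_cols].fillna(0) < 0).any().any():
        raise DataError("driver values must be nonnegative")


def default_step_down_order(ledger: pd.DataFrame) -> tuple[str, ...]:
    """Overhead centers in descending direct-cost order (the default)."""
    overhead = ledger[ledger["kind"] == "overhead"]
    return tuple(
        overhead.sort_values("direct_cost", ascending=False)["center"].tolist()
    )


def step_down_allocate(
    ledger: pd.DataFrame, order: tuple[str, ...] | list[str] | None = None
) -> dict[str, float]:
    """Step-allocate overhead pools; return allocated overhead per activity center.

    Each pool = the overhead center's direct cost plus anything already
    allocated to it. It is split over the not-yet-allocated centers
    (later overhead centers plus all activity centers) proportionally
    to that center's value of the pool's driver. Conservation — the sum
    over activity centers equals the total overhead entering the system
    — holds to floating-point precision.
    """
    validate_ledger(ledger)
    overhead = ledger[ledger["kind"] == "overhead"].set_index("center")
    activity = ledger[ledger["kind"] == "activity"].set_index("center")
    if order is None:
        order = default_step_down_order(ledger)
    order = tuple(order)
    unknown = set(order) - set(overhead.index)
    if unknown:
        raise ConfigurationError(
            f"step-down order names unknown overhead centers: {sorted(unknown)}"
        )
    missing = set(overhead.index) - set(order)
    if missing:
        raise ConfigurationError(
            f"step-down order must cover all overhead centers; missing {sorted(missing)}"
        )

    received: dict[str, float] = {c: 0.0 for c in ledger["center"]}
    for i, name in enumerate(order):
        pool = float(overhead.loc[name, "direct_cost"]) + received[name]
        driver_col = DRIVER_PREFIX + str(overhead.loc[name, "driver"])
        later_overhead = list(order[i + 1 :])
        recipients = later_overhead + list(activity.index)
        weights = (
            ledger.set_index("center")
            .loc[recipients, driver_col]
            .fillna(0.0)
            .astype(float)
        )
        total = float(weights.sum())
        if total <= 0:
            raise ComputationError(
                f"cannot allocate overhead pool {name!r}: all {driver_col!r} "
                "values of the remaining centers are zero"
            )
        for rec, w in weights.items():
            received[rec] += pool * float(w) / total
    return {c: received[c] for c in activity.index}


def allocation_order_report(
    ledger: pd.DataFrame, max_overhead: int = 4
) -> pd.DataFrame:
    """Allocated overhead per activity center for every step-down order.

    Step-down results are order-dependent; this enumerates all
    permutations of the overhead centers (refused above
    ``max_overhead`` — factorial growth) so the sensitivity of the
    allocation to the declared order can be inspected. Each row also
    reports the conservation error, which must be ~0 regardless of
    order.
    """
    overhead_names = ledger.loc[ledger["kind"] == "overhead", "center"].tolist()
    if len(overhead_names) > max_overhead:
        raise ConfigurationError(
            f"{len(overhead_names)} overhead centers; permutation report limited "
            f"to {max_overhead}"
        )
    pool_total = float(
        ledger.loc[ledger["kind"] == "overhead", "direct_cost"].sum()
    )
    rows = []
    for perm in itertools.permutations(overhead_names):
        alloc = step_down_allocate(ledger, order=perm)
        row: dict[str, object] = {"order": " > ".join(perm)}
        row.update(alloc)
        row["conservation_error"] = sum(alloc.values()) - pool_total
        rows.append(row)
    return pd.DataFrame(rows)


def unit_costs(
    ledger: pd.DataFrame, allocations: dict[str, float]
) -> pd.DataFrame:
    """Unit cost per service category: (direct + allocated) / volume.

    When several activity centers share one category (e.g. seven
    ambulatory clinics), the category unit cost is the volume-weighted
    mean of the center unit costs, i.e. total category cost over total
    category volume — so multiplying back by category-level utilization
    reproduces the sum over centers.

    Returns a DataFrame indexed by category with columns
    ``unit_cost``, ``total_cost``, ``volume``, ``year``.
    """
    validate_ledger(ledger)
    activity = ledger[ledger["kind"] == "activity"].set_index("center")
    missing = set(activity.index) - set(allocations)
    if missing:
        raise ConfigurationError(
            f"allocations missing for activity centers: {sorted(missing)}"
        )
    zero_vol = activity.index[activity["volume"] == 0].tolist()
    if zero_vol:
        raise ComputationError(
            f"unit cost undefined for zero-volume centers: {zero_vol}"
        )
    total = activity["direct_cost"].astype(float) + pd.Series(allocations).reindex(
        activity.index
    )
    frame = pd.DataFrame(
        {
            "category": activity["category"],
            "total_cost": total,
            "volume": activity["volume"].astype(float),
            "year": activity["year"],
        }
    )
    agg = frame.groupby("category").agg(
        total_cost=("total_cost", "sum"),
        volume=("volume", "sum"),
        year=("year", "max"),
    )
    agg["unit_cost"] = agg["total_cost"] / agg["volume"]
    return agg[["unit_cost", "total_cost", "volume", "year"]]


def straight_line_depreciation(capital: float, useful_life_years: float) -> float:
    """Annual depreciation of startup capital over its useful life."""
    if capital < 0:
        raise ConfigurationError("capital must be nonnegative")
    if useful_life_years <= 0:
        raise ConfigurationError("useful life must be positive")
    return capital / useful_life_years


def adjust_to_base_year(
    amount: float,
    from_year: int,
    deflator: dict[int, float] | None,
    base_year: int,
) -> float:
    """Convert a money amount between calendar years via a price index.

    ``deflator`` maps year -> index. A ``None`` deflator is the
    identity (inputs already in base-year dollars) and is only valid
    when ``from_year == base_year``.
    """
    if from_year == base_year:
        return float(amount)
    if deflator is None:
        raise ConfigurationError(
            f"no deflator supplied but amount is in {from_year} dollars "
            f"and base year is {base_year}"
        )
    for y in (from_year, base_year):
        if y not in deflator:
            raise ConfigurationError(f"deflator has no index for year {y}")
    return float(amount) * deflator[base_year] / deflator[from_year]


# ---------------------------------------------------------------------------
# Intervention program costing


@dataclass(frozen=True)
class InterventionLedger:
    """Finance ledger of the home-visit intervention program.

    Variable (consumable) costs are recorded per quarter together with
    the visit counts of that quarter; fixed components — the staff
    salary share, depreciated startup capital, the opportunity cost of
    donated space, and other overhead — are annual figures. Monthly
    visit counts identify the busiest month, whose throughput defines
    the program's full capacity.
    """

    consumables_by_quarter: tuple[tuple[str, float], ...]
    visits_by_quarter: tuple[tuple[str, float], ...]
    startup_capital: float
    staff_salary_share: float  # per year
    space_opportunity_cost: float  # per year
    visits_by_month: tuple[tuple[str, float], ...]
    participants: int
    useful_life_years: float = 5.0
    other_overhead: float = 0.0  # per year
    year: int = 2012

    def __post_init__(self) -> None:
        if self.participants <= 0:
            raise ConfigurationError("participants must be positive")
        if self.useful_life_years <= 0:
            raise ConfigurationError("useful life must be positive")
        for name, value in [
            ("startup_capital", self.startup_capital),
            ("staff_salary_share", self.staff_salary_share),
            ("space_opportunity_cost", self.space_opportunity_cost),
            ("other_overhead", self.other_overhead),
        ]:
            if value < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not self.visits_by_month:
            raise ConfigurationError("at least one month of visit counts required")
        if any(v < 0 for _, v in self.visits_by_month):
            raise ConfigurationError("monthly visit counts must be nonnegative")
        if any(v < 0 for _, v in self.visits_by_quarter):
            raise ConfigurationError("quarterly visit counts must be nonnegative")
        if any(c < 0 for _, c in self.consumables_by_quarter):
            raise ConfigurationError("consumable costs must be nonnegative")
        if len(self.consumables_by_quarter) != len(self.visits_by_quarter):
            raise ConfigurationError(
                "consumables and visits must cover the same quarters"
            )

    @property
    def total_visits(self) -> float:
        return float(sum(v for _, v in self.visits_by_month))

    @property
    def busiest_month_visits(self) -> float:
        return float(max(v for _, v in self.visits_by_month))


@dataclass(frozen=True)
class InterventionCostBreakdown:
    staffing: float
    equipment: float
    space: float
    other: float
    consumables: float

    @property
    def total(self) -> float:
        return self.staffing + self.equipment + self.space + self.other + self.consumables

    def as_dict(self) -> dict[str, float]:
        return {
            "staffing": self.staffing,
            "equipment": self.equipment,
            "space": self.space,
            "other": self.other,
            "consumables": self.consumables,
            "total": self.total,
        }


def intervention_cost_per_participant(
    ledger: InterventionLedger, capacity_rule: str = "busiest_month"
) -> InterventionCostBreakdown:
    """Direct program cost per participant, split into components.

    Variable costs: each quarter's consumables divided by that
    quarter's visits gives a variable cost per visit, applied to the
    mean per-participant visits of the quarter — summing to total
    consumables over participants.

    Fixed costs (annual staffing share, straight-line depreciation of
    startup capital, donated-space opportunity cost, other overhead)
    are converted to a monthly rate and divided by the visit count of
    the busiest month — costing the program as if it ran at full
    capacity, as an ongoing service would ("busiest_month" rule). The
    "annual_average" rule divides the annual figure by total annual
    visits instead. Either per-visit rate is then multiplied by the
    mean visits per participant.
    """
    if capacity_rule not in ("busiest_month", "annual_average"):
        raise ConfigurationError(
            "capacity_rule must be 'busiest_month' or 'annual_average'"
        )

    mean_visits = ledger.total_visits / ledger.participants

    # variable component
    consumables = 0.0
    for (q, cost), (q2, visits) in zip(
        ledger.consumables_by_quarter, ledger.visits_by_quarter
    ):
        if q != q2:
            raise ConfigurationError(
                f"quarter mismatch between consumables ({q}) and visits ({q2})"
            )
        if visits == 0:
            if cost > 0:
                raise ComputationError(
                    f"quarter {q}: consumables spent with zero visits"
                )
            continue
        per_visit = cost / visits
        consumables += per_visit * (visits / ledger.participants)

    # fixed components
    annual_fixed = {
        "staffing": ledger.staff_salary_share,
        "equipment": straight_line_depreciation(
            ledger.startup_capital, ledger.useful_life_years
        ),
        "space": ledger.space_opportunity_cost,
        "other": ledger.other_overhead,
    }
    if all(v == 0 for v in annual_fixed.values()):
        per_visit_fixed = {k: 0.0 for k in annual_fixed}
    else:
        if capacity_rule == "busiest_month":
            capacity = ledger.busiest_month_visits
            if capacity == 0:
                raise ComputationError(
                    "fixed cost per visit undefined: zero visits in the busiest month"
                )
            per_visit_fixed = {k: (v / 12.0) / capacity for k, v in annual_fixed.items()}
        else:
            if ledger.total_visits == 0:
                raise ComputationError(
                    "fixed cost per visit undefined: zero annual visits"
                )
            per_visit_fixed = {
                k: v / ledger.total_visits for k, v in annual_fixed.items()
            }

    return InterventionCostBreakdown(
        staffing=per_visit_fixed["staffing"] * mean_visits,
        equipment=per_visit_fixed["equipment"] * mean_visits,
        space=per_visit_fixed["space"] * mean_visits,
        other=per_visit_fixed["other"] * mean_visits,
        consumables=consumables,
    )
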