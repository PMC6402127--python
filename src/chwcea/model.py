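"""The cost-effectiveness model object and its fitted results.

:class:`DiabetesCEA` is built from the four input tables plus an
:class:`~chwcea.config.AnalysisConfig`; ``fit()`` runs the full
pipeline — step-down costing, unit costs, intervention program
costing, utilization difference-in-differences, indirect time
valuation, QALY modelling, ICERs and threshold decisions — and
returns a :class:`CEAResults` carrying every intermediate table, a
``summary()`` report, and one-way sensitivity analysis.

Usage::

    from chwcea import DiabetesCEA

    res = DiabetesCEA.from_fixture().fit()
    print(res.summary())
    sens = res.sensitivity({"utility_decrement": [0.03, 0.17]})
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from math import isnan, nan
from pathlib import Path

import pandas as pd

from . import cea as _cea
from . import costing as _costing
from . import did as _did
from . import io as _io
from . import qaly as _qaly
from . import timevalue as _tv
from .config import AnalysisConfig
from .exceptions import CEAError, DataError
from .simulate import observed_hba1c_reduction
from .taxonomy import DEFAULT_TAXONOMY

logger = logging.getLogger(__name__)

#: Sensitivity-analysis parameters understood by ``CEAResults.sensitivity``.
SENSITIVITY_PARAMETERS = (
    "hba1c_reduction",
    "utility_decrement",
    "incremental_cost_multiplier",
)


def _frame_digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


class DiabetesCEA:
    """Cost-effectiveness model of a CHW diabetes intervention vs standard care.

    Parameters
    ----------
    patients, encounters, finance_ledger : DataFrame
        Trial cohort, pre/post encounter stream, hospital cost-center
        ledger (see :mod:`chwcea.io` for the schemas).
    intervention_ledger : InterventionLedger
        Program finance ledger.
    config : AnalysisConfig, optional
        Analysis settings; defaults to the base-case configuration.
    """

    def __init__(
        self,
        patients: pd.DataFrame,
        encounters: pd.DataFrame,
        finance_ledger: pd.DataFrame,
        intervention_ledger: _costing.InterventionLedger,
        config: AnalysisConfig | None = None,
        taxonomy=None,
    ) -> None:
        self.patients = patients
        self.encounters = encounters
        self.finance_ledger = finance_ledger
        self.intervention_ledger = intervention_ledger
        self.config = config or AnalysisConfig()
        self.taxonomy = taxonomy or DEFAULT_TAXONOMY

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_fixture(cls) -> "DiabetesCEA":
        """Model over the deterministic study-calibrated dataset."""
        from .datasets import study_fixture

        b = study_fixture()
        return cls(
            b.patients, b.encounters, b.finance_ledger, b.intervention_ledger, b.config
        )

    @classmethod
    def from_simulation(
        cls, params=None, config: AnalysisConfig | None = None, seed: int = 0
    ) -> "DiabetesCEA":
        """Model over freshly simulated trial data (see :mod:`chwcea.simulate`)."""
        from . import simulate as sim

        params = params or sim.CohortParams(seed=seed)
        patients = sim.generate_cohort(params)
        encounters = sim.generate_encounters(patients, seed=params.seed + 1)
        ledger = sim.generate_finance_ledger(seed=params.seed + 2)
        iv = sim.generate_intervention_ledger(
            participants=params.n_chw, seed=params.seed + 3
        )
        config = config or AnalysisConfig(
            person_years=params.person_years,
            intervention_minutes_per_patient=602.0,
        )
        return cls(patients, encounters, ledger, iv, config)

    @classmethod
    def from_csv(
        cls,
        patients_path,
        encounters_path,
        finance_ledger_path,
        intervention_ledger_path,
        config_path=None,
    ) -> "DiabetesCEA":
        config = (
            AnalysisConfig.from_yaml(config_path) if config_path else AnalysisConfig()
        )
        return cls(
            _io.read_patients(patients_path),
            _io.read_encounters(encounters_path),
            _io.read_finance_ledger(finance_ledger_path),
            _io.read_intervention_ledger(intervention_ledger_path),
            config,
        )

    @classmethod
    def from_directory(cls, in_dir, config_path=None) -> "DiabetesCEA":
        d = Path(in_dir)
        cfg = config_path or (
            d / "config.yaml" if (d / "config.yaml").exists() else None
        )
        return cls.from_csv(
            d / "patients.csv",
            d / "encounters.csv",
            d / "finance_ledger.csv",
            d / "intervention_ledger.csv",
            cfg,
        )

    # -- fitting ----------------------------------------------------------

    def fit(self, **overrides) -> "CEAResults":
        """Run the full pipeline; ``overrides`` adjust single parameters.

        Supported overrides: ``hba1c_reduction`` (HbA1c points),
        ``utility_decrement`` (utility per point),
        ``incremental_cost_multiplier`` (scales the incremental cost;
        supported for exploratory sensitivity only).
        """
        cfg = self.config
        unknown = set(overrides) - set(SENSITIVITY_PARAMETERS)
        if unknown:
            raise CEAError(f"unknown fit override(s): {sorted(unknown)}")
        if "hba1c_reduction" in overrides:
            cfg = cfg.replace(hba1c_reduction=float(overrides["hba1c_reduction"]))
        if "utility_decrement" in overrides:
            um = cfg.utility_model
            cfg = cfg.replace(
                utility_model=type(um)(
                    decrement_per_hba1c_point=float(overrides["utility_decrement"]),
                    label="override",
                    horizon_years=um.horizon_years,
                )
            )
        cost_multiplier = float(overrides.get("incremental_cost_multiplier", 1.0))

        # 1. hospital costing
        order = cfg.step_down_order or _costing.default_step_down_order(
            self.finance_ledger
        )
        allocations = _costing.step_down_allocate(self.finance_ledger, order=order)
        unit_cost_table = _costing.unit_costs(self.finance_ledger, allocations)
        unit_cost_table = unit_cost_table.assign(
            unit_cost=[
                _costing.adjust_to_base_year(
                    uc, int(yr), cfg.deflator, cfg.base_year
                )
                for uc, yr in zip(unit_cost_table["unit_cost"], unit_cost_table["year"])
            ]
        )

        # 2. intervention program costing
        breakdown = _costing.intervention_cost_per_participant(
            self.intervention_ledger, capacity_rule=cfg.capacity_rule
        )
        intervention_cost = _costing.adjust_to_base_year(
            breakdown.total, self.intervention_ledger.year, cfg.deflator, cfg.base_year
        )

        # 3. utilization DiD
        person_years = cfg.person_years or _did.person_years_from_patients(
            self.patients
        )
        udid = _did.utilization_did(
            self.encounters,
            self.patients,
            person_years,
            taxonomy=self.taxonomy,
            exclude=cfg.exclude_categories,
        )

        # 4. indirect patient time
        group_did = (
            udid.groupby(
                udid.index.map(lambda k: self.taxonomy[k].group.value)
            ).sum()
        )
        iv_hours = cfg.intervention_minutes_per_patient / 60.0
        iv_indirect = _tv.intervention_indirect_cost(
            cfg.intervention_minutes_per_patient, cfg.time_policy
        )
        own_medical = _tv.medical_indirect_did(group_did.to_dict(), cfg.time_policy)
        med_cost = (
            cfg.medical_indirect_cost_override
            if cfg.medical_indirect_cost_override is not None
            else own_medical.cost_did
        )
        med_hours = (
            cfg.medical_indirect_hours_override
            if cfg.medical_indirect_hours_override is not None
            else own_medical.hours_did
        )
        indirect = _did.IndirectRows(
            intervention_cost=iv_indirect,
            medical_cost=med_cost,
            intervention_hours=iv_hours,
            medical_hours=med_hours,
        )

        # 5. cost DiD table
        did_table = _did.cost_did(
            udid,
            unit_cost_table,
            intervention_cost,
            indirect,
            person_years=person_years,
            taxonomy=self.taxonomy,
        )
        incremental_cost = did_table.total * cost_multiplier

        # 6. effectiveness
        reduction = (
            cfg.hba1c_reduction
            if cfg.hba1c_reduction is not None
            else observed_hba1c_reduction(self.patients)
        )
        qalys = _qaly.qalys_gained(reduction, cfg.utility_model)

        # 7. ICERs and decisions
        icer_hba1c = _cea.icer(incremental_cost, reduction)
        icer_qaly = _cea.icer(incremental_cost, qalys)
        decisions = _cea.threshold_decisions(icer_qaly, cfg.thresholds)

        provenance = {
            "config": cfg.digest(),
            "patients": _frame_digest(self.patients),
            "encounters": _frame_digest(self.encounters),
            "finance_ledger": _frame_digest(self.finance_ledger),
        }
        logger.info("fit complete; provenance %s", provenance)

        return CEAResults(
            model=self,
            config_used=cfg,
            allocations=allocations,
            unit_cost_table=unit_cost_table,
            intervention_breakdown=breakdown,
            person_years=dict(person_years),
            did_table=did_table,
            own_medical_indirect=own_medical,
            incremental_cost=incremental_cost,
            hba1c_reduction=float(reduction),
            qalys=float(qalys),
            _icer_hba1c=icer_hba1c,
            _icer_qaly=icer_qaly,
            decisions=decisions,
            provenance=provenance,
        )


# ---------------------------------------------------------------------------


def _money(x: float) -> str:
    """Money with the thin-space thousands style used in the report."""
    if isinstance(x, float) and isnan(x):
        return "—"
    sign = "-" if x < 0 else ""
    whole, frac = f"{abs(x):,.2f}".split(".")
    return f"{sign}${whole.replace(',', ' ')}.{frac}"


@dataclass(frozen=True)
class CEAResults:
    """Fitted results: estimates, tables, decisions, diagnostics."""

    model: DiabetesCEA
    config_used: AnalysisConfig
    allocations: dict[str, float]
    unit_cost_table: pd.DataFrame
    intervention_breakdown: _costing.InterventionCostBreakdown
    person_years: dict[str, float]
    did_table: _did.DiDTable
    own_medical_indirect: _tv.MedicalIndirectDiD
    incremental_cost: float
    hba1c_reduction: float
    qalys: float
    _icer_hba1c: _cea.ICER
    _icer_qaly: _cea.ICER
    decisions: dict[str, bool]
    provenance: dict[str, str] = field(default_factory=dict)

    # -- scalar views -----------------------------------------------------

    @property
    def icer_hba1c(self) -> float:
        """USD per HbA1c percentage point reduced (NaN unless interior)."""
        return self._icer_hba1c.value

    @property
    def icer_qaly(self) -> float:
        """USD per QALY gained (NaN unless interior)."""
        return self._icer_qaly.value

    @property
    def dominance(self) -> _cea.Dominance:
        return self._icer_qaly.dominance

    # -- sensitivity ------------------------------------------------------

    def sensitivity(self, param_grid: dict) -> _cea.SensitivityResult:
        """One-way sensitivity: re-fit varying one parameter at a time."""
        def refit(param: str, value: float):
            if param not in SENSITIVITY_PARAMETERS:
                raise CEAError(
                    f"unknown sensitivity parameter {param!r}; "
                    f"supported: {SENSITIVITY_PARAMETERS}"
                )
            return self.model.fit(**{param: value})

        return _cea.one_way_sensitivity(refit, param_grid, self.icer_qaly)

    # -- reporting --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "incremental_cost": self.incremental_cost,
            "hba1c_reduction": self.hba1c_reduction,
            "qalys_gained": self.qalys,
            "icer_hba1c": self.icer_hba1c,
            "icer_qaly": self.icer_qaly,
            "dominance": self.dominance.value,
            "decisions": dict(self.decisions),
            "person_years": dict(self.person_years),
            "intervention_cost_breakdown": self.intervention_breakdown.as_dict(),
            "unit_costs": self.unit_cost_table["unit_cost"].to_dict(),
            "did_table": self.did_table.to_frame().to_dict(orient="records"),
            "provenance": dict(self.provenance),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def summary(self) -> str:
        """Human-readable report: cost-effectiveness block and DiD table.

        Money and utilization shown at 2 decimals, QALYs at 5;
        internal values keep full precision.
        """
        c = self
        lines = []
        add = lines.append
        rule = "=" * 72
        add(rule)
        add("Community health worker diabetes intervention vs standard care")
        add("Societal perspective; costs in "
            f"{c.config_used.base_year} USD per patient per year")
        add(rule)
        add("")
        add("Incremental cost-effectiveness")
        add("-" * 72)
        add(f"{'Incremental cost':38s}{_money(c.incremental_cost):>16s}")
        add(f"{'HbA1c reduced (percentage points)':38s}{c.hba1c_reduction:16.2f}")
        add(f"{'QALYs gained':38s}{c.qalys:16.5f}")
        add(f"{'ICER (per HbA1c point)':38s}{_money(c.icer_hba1c):>16s}")
        add(f"{'ICER (per QALY)':38s}{_money(c.icer_qaly):>16s}")
        add(f"{'Dominance classification':38s}{c.dominance.value:>16s}")
        add("")
        add("Service utilization and cost differences (per patient per year)")
        add("-" * 72)
        add(f"{'':38s}{'Utilization DiD':>16s}{'Cost DiD':>16s}")
        for label, row in c.did_table.by_group().iterrows():
            add(
                f"{label:38s}{row['utilization_did']:16.2f}"
                f"{_money(row['cost_did']):>16s}"
            )
        ind = c.did_table.indirect
        add(
            f"{'Intervention indirect (hours)':38s}{ind.intervention_hours:16.2f}"
            f"{_money(ind.intervention_cost):>16s}"
        )
        add(
            f"{'Medical indirect (hours)':38s}{ind.medical_hours:16.2f}"
            f"{_money(ind.medical_cost):>16s}"
        )
        add(f"{'Total':38s}{'':16s}{_money(c.did_table.total):>16s}")
        add("")
        add("Willingness-to-pay decisions (cost-effective iff ICER <= threshold)")
        add("-" * 72)
        for label, lam in sorted(
            c.config_used.thresholds.entries.items(), key=lambda kv: kv[1]
        ):
            verdict = "cost-effective" if c.decisions[label] else "not cost-effective"
            add(f"{label:24s}{_money(lam):>14s}   {verdict}")
        add("")
        add(
            f"Person-years: intervention {c.person_years.get('chw', nan):.0f}, "
            f"control {c.person_years.get('control', nan):.0f}"
            f" | config {c.provenance.get('config', '?')}"
        )
        add(rule)
        return "\n".join(lines)


def run_pipeline(config_or_dir, out_dir=None) -> CEAResults:
    """Convenience wrapper: build a model from a data directory and fit.

    ``config_or_dir`` is a directory holding the four CSV tables (and
    optionally ``config.yaml``). Writes ``report.txt``, ``cea.json``
    and ``did_table.csv`` into ``out_dir`` when given.
    """
    model = DiabetesCEA.from_directory(config_or_dir)
    results = model.fit()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(results.summary() + "\n", encoding="utf-8")
        results.to_json(out / "cea.json")
        _io.write_did_table(results.did_table.to_frame(), out / "did_table.csv")
    return results
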