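"""CSV schemas and round-trip readers/writers for every pipeline table.

All tables are plain UTF-8 CSV. Readers validate headers strictly
(missing or unexpected columns raise :class:`SchemaError` naming the
column) and report the 1-based file line of the first malformed value.
Writers emit full precision via :func:`repr`-style float formatting so
write-then-read is the identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .costing import DRIVER_PREFIX, LEDGER_BASE_COLUMNS, InterventionLedger
from .exceptions import DataError, SchemaError
from .simulate import ENCOUNTER_COLUMNS, PATIENT_COLUMNS

def _FLOAT_FMT(v: float) -> str:  # shortest exact round-trip representation
    return repr(float(v))


def _check_columns(
    df: pd.DataFrame, required: list[str], path, allow_prefix: str | None = None
) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [
        c
        for c in df.columns
        if c not in required and not (allow_prefix and c.startswith(allow_prefix))
    ]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise DataError(
                f"{path}: line {line}: malformed numeric value "
                f"{df.loc[bad.idxmax(), col]!r} in column {col!r}"
            )
        df[col] = coerced
    return df


def write_patients(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, PATIENT_COLUMNS, path)
    df["hba1c_followup"] = df["hba1c_followup"].replace("", np.nan)
    df = _coerce_numeric(df, ["age", "hba1c_baseline", "hba1c_followup"], path)
    df["retained"] = df["retained"].map(
        {"True": True, "False": False, "true": True, "false": False}
    )
    if df["retained"].isna().any():
        line = int(df["retained"].isna().idxmax()) + 2
        raise DataError(f"{path}: line {line}: malformed boolean in 'retained'")
    return df[PATIENT_COLUMNS]


def write_encounters(encounters: pd.DataFrame, path) -> None:
    encounters.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_encounters(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, ENCOUNTER_COLUMNS, path)
    df = _coerce_numeric(df, ["quantity"], path)
    return df[ENCOUNTER_COLUMNS]


def write_finance_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_finance_ledger(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, LEDGER_BASE_COLUMNS, path, allow_prefix=DRIVER_PREFIX)
    driver_cols = [c for c in df.columns if c.startswith(DRIVER_PREFIX)]
    df["volume"] = df["volume"].replace("", np.nan)
    for c in driver_cols:
        df[c] = df[c].replace("", np.nan)
    df = _coerce_numeric(df, ["direct_cost", "year", "volume", *driver_cols], path)
    df["year"] = df["year"].astype(int)
    return df


def write_unit_costs(unit_cost_table: pd.DataFrame, path) -> None:
    unit_cost_table.reset_index().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_unit_costs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, ["category", "unit_cost", "total_cost", "volume", "year"], path)
    df = _coerce_numeric(df, ["unit_cost", "total_cost", "volume", "year"], path)
    return df.set_index("category")


def write_did_table(did_frame: pd.DataFrame, path) -> None:
    did_frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_did_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, ["category", "group", "utilization_did", "cost_did"], path)
    df["utilization_did"] = df["utilization_did"].replace("", np.nan)
    return _coerce_numeric(df, ["utilization_did", "cost_did"], path)


# ---------------------------------------------------------------------------
# Intervention ledger: long (item, period, value) layout

_SCALAR_ITEMS = {
    "startup_capital",
    "staff_salary_share",
    "space_opportunity_cost",
    "other_overhead",
    "useful_life_years",
    "participants",
    "year",
}


def write_intervention_ledger(ledger: InterventionLedger, path) -> None:
    rows = []
    for q, v in ledger.consumables_by_quarter:
        rows.append(("consumables", q, v))
    for q, v in ledger.visits_by_quarter:
        rows.append(("visits_quarter", q, v))
    for m, v in ledger.visits_by_month:
        rows.append(("visits_month", m, v))
    for item in sorted(_SCALAR_ITEMS):
        rows.append((item, "", getattr(ledger, item)))
    pd.DataFrame(rows, columns=["item", "period", "value"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_intervention_ledger(path) -> InterventionLedger:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, ["item", "period", "value"], path)
    df = _coerce_numeric(df, ["value"], path)

    def series(item):
        sub = df[df["item"] == item]
        return tuple(zip(sub["period"], sub["value"].astype(float)))

    scalars = {}
    for item in _SCALAR_ITEMS:
        sub = df[df["item"] == item]
        if len(sub) != 1:
            raise SchemaError(f"{path}: expected exactly one {item!r} row")
        scalars[item] = float(sub["value"].iloc[0])
    scalars["participants"] = int(scalars["participants"])
    scalars["year"] = int(scalars["year"])
    return InterventionLedger(
        consumables_by_quarter=series("consumables"),
        visits_by_quarter=series("visits_quarter"),
        visits_by_month=series("visits_month"),
        **scalars,
    )


# ---------------------------------------------------------------------------


def write_bundle(bundle, out_dir) -> dict[str, Path]:
    """Write a full input bundle to a directory; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "encounters": out / "encounters.csv",
        "finance_ledger": out / "finance_ledger.csv",
        "intervention_ledger": out / "intervention_ledger.csv",
        "config": out / "config.yaml",
    }
    write_patients(bundle.patients, paths["patients"])
    write_encounters(bundle.encounters, paths["encounters"])
    write_finance_ledger(bundle.finance_ledger, paths["finance_ledger"])
    write_intervention_ledger(bundle.intervention_ledger, paths["intervention_ledger"])
    bundle.config.to_yaml(paths["config"])
    return paths
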