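import pandas as pd
import pytest

from chwcea import DiabetesCEA, study_fixture
from chwcea.costing import DRIVER_PREFIX


@pytest.fixture(scope="session")
def bundle():
    return study_fixture()


@pytest.fixture(scope="session")
def fixture_results():
    return DiabetesCEA.from_fixture().fit()


def make_ledger(overheads, activities):
    """Build a finance-ledger frame from compact tuples.

    overheads: (name, driver, cost, {driver_name: value})
    activities: (name, category, direct, volume, {driver_name: value})
    """
    driver_names = sorted(
        {o[1] for o in overheads}
        | {k for o in overheads for k in o[3]}
        | {k for a in activities for k in a[4]}
    )
    rows = []
    for name, driver, cost, drv in overheads:
        row = {
            "center": name, "kind": "overhead", "direct_cost": cost,
            "year": 2012, "volume": float("nan"), "category": "", "driver": driver,
        }
        for d in driver_names:
            row[DRIVER_PREFIX + d] = drv.get(d, 0.0)
        rows.append(row)
    for name, category, direct, volume, drv in activities:
        row = {
            "center": name, "kind": "activity", "direct_cost": direct,
            "year": 2012, "volume": volume, "category": category, "driver": "",
        }
        for d in driver_names:
            row[DRIVER_PREFIX + d] = drv.get(d, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def ledger_factory():
    return make_ledger
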