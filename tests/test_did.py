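"""Utilization difference-in-differences and cost conversion."""

import numpy as np
import pandas as pd
import pytest

from chwcea import ConfigurationError, DataError, cost_did, utilization_did
from chwcea.did import IndirectRows, person_years_from_patients


def patients_frame(rows):
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "cluster_id": "c0",
                "arm": arm,
                "age": 55.0,
                "sex": "female",
                "hba1c_baseline": 9.5,
                "hba1c_followup": 9.5,
                "retained": True,
            }
            for pid, arm in rows
        ]
    )


def encounters_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "period", "category", "quantity"])


PY1 = {"chw": 1.0, "control": 1.0}


class TestUtilizationDiD:
    def test_matches_per_patient_enumeration(self):
        """Hand-set quantities: chw 2 pre -> 1 post, control 1 -> 1."""
        pats = patients_frame([("a", "chw"), ("b", "control")])
        enc = encounters_frame(
            [
                ("a", "pre", "ed", 2.0),
                ("a", "post", "ed", 1.0),
                ("b", "pre", "ed", 1.0),
                ("b", "post", "ed", 1.0),
            ]
        )
        # brute force: sum per arm/period then difference the differences
        chw_change = 1.0 - 2.0
        ctl_change = 1.0 - 1.0
        expected = chw_change / 1.0 - ctl_change / 1.0
        did = utilization_did(enc, pats, PY1)
        assert did["ed"] == pytest.approx(expected)

    def test_identical_arms_give_zero_everywhere(self):
        pats = patients_frame([("a", "chw"), ("b", "control")])
        enc = encounters_frame(
            [
                (p, per, cat, 3.0)
                for p in ("a", "b")
                for per in ("pre", "post")
                for cat in ("ed", "ambulatory", "surgery")
            ]
        )
        did = utilization_did(enc, pats, PY1)
        assert (did.abs() < 1e-12).all()

    def test_person_year_normalization(self):
        pats = patients_frame([("a", "chw"), ("b", "control")])
        enc = encounters_frame([("a", "post", "ed", 50.0)])
        did = utilization_did(enc, pats, {"chw": 100.0, "control": 163.0})
        assert did["ed"] == pytest.approx(0.5)

    def test_fixture_reproduces_published_aggregates(self, bundle, fixture_results):
        detail = fixture_results.did_table.detail
        assert detail.loc["intervention", "utilization_did"] == pytest.approx(1.00)
        assert detail.loc["ed", "utilization_did"] == pytest.approx(-0.61)
        assert detail.loc["ambulatory", "utilization_did"] == pytest.approx(-0.18)
        assert detail.loc["surgery", "utilization_did"] == pytest.approx(-0.10)
        hosp = detail[detail["group"] == "hospitalization"]["utilization_did"].sum()
        assert hosp == pytest.approx(-0.14)
        assert detail.loc["icu", "utilization_did"] == pytest.approx(0.06)

    def test_exclusions_are_dropped_before_aggregation(self, bundle):
        cfg = bundle.config
        did_excl = utilization_did(
            bundle.encounters, bundle.patients, cfg.person_years,
            exclude=cfg.exclude_categories,
        )
        did_incl = utilization_did(
            bundle.encounters, bundle.patients, cfg.person_years
        )
        assert "maternity_ward" not in did_excl.index
        assert did_incl["maternity_ward"] == pytest.approx(0.02)

    def test_unknown_arm_and_unknown_patient_are_data_errors(self):
        pats = patients_frame([("a", "chw"), ("b", "placebo")])
        enc = encounters_frame([("a", "pre", "ed", 1.0)])
        with pytest.raises(DataError, match="arm"):
            utilization_did(enc, pats, PY1)
        pats = patients_frame([("a", "chw"), ("b", "control")])
        enc = encounters_frame([("ghost", "pre", "ed", 1.0)])
        with pytest.raises(DataError, match="unknown patients"):
            utilization_did(enc, pats, PY1)

    def test_unknown_category_is_configuration_error(self):
        pats = patients_frame([("a", "chw"), ("b", "control")])
        enc = encounters_frame([("a", "pre", "helipad", 1.0)])
        with pytest.raises(ConfigurationError, match="helipad"):
            utilization_did(enc, pats, PY1)

    def test_nonpositive_person_years_rejected(self):
        pats = patients_frame([("a", "chw"), ("b", "control")])
        enc = encounters_frame([("a", "pre", "ed", 1.0)])
        with pytest.raises(DataError, match="person-years"):
            utilization_did(enc, pats, {"chw": 0.0, "control": 1.0})

    def test_person_years_helper_counts_partial_followup(self):
        pats = patients_frame([("a", "chw"), ("b", "chw"), ("c", "control")])
        pats.loc[1, "retained"] = False
        py = person_years_from_patients(pats)
        assert py == {"chw": pytest.approx(1.5), "control": pytest.approx(1.0)}


def unit_cost_frame(entries):
    return pd.DataFrame(
        {"unit_cost": pd.Series(entries), "total_cost": 0.0, "volume": 1.0, "year": 2012}
    )


class TestCostDiD:
    def test_multiplication_by_unit_cost(self):
        udid = pd.Series({"ed": -0.61})
        table = cost_did(
            udid, unit_cost_frame({"ed": 83.77 / 0.61}), 0.0, IndirectRows(0.0, 0.0)
        )
        assert table.detail.loc["ed", "cost_did"] == pytest.approx(-83.77)

    def test_zero_unit_costs_leave_only_indirect(self):
        udid = pd.Series({"ed": -0.61, "ambulatory": 5.0})
        table = cost_did(
            udid, unit_cost_frame({"ed": 0.0, "ambulatory": 0.0}), 0.0,
            IndirectRows(intervention_cost=10.0, medical_cost=-2.0),
        )
        assert table.total == pytest.approx(8.0)

    def test_linearity_in_unit_costs_and_utilization(self):
        udid = pd.Series({"ed": -0.4, "surgery": 0.3})
        uc = unit_cost_frame({"ed": 100.0, "surgery": 50.0})
        base = cost_did(udid, uc, 0.0, IndirectRows(0.0, 0.0))
        doubled_uc = cost_did(udid, unit_cost_frame({"ed": 200.0, "surgery": 100.0}),
                              0.0, IndirectRows(0.0, 0.0))
        doubled_u = cost_did(2 * udid, uc, 0.0, IndirectRows(0.0, 0.0))
        assert doubled_uc.detail["cost_did"].sum() == pytest.approx(
            2 * base.detail["cost_did"].sum()
        )
        assert doubled_u.detail["cost_did"].sum() == pytest.approx(
            2 * base.detail["cost_did"].sum()
        )

    def test_sign_coherence(self):
        udid = pd.Series({"ed": -1.3})
        table = cost_did(udid, unit_cost_frame({"ed": 42.0}), 0.0, IndirectRows(0.0, 0.0))
        assert table.detail.loc["ed", "cost_did"] < 0

    def test_expensive_icu_increase_outweighs_day_reduction(self):
        """Ward-by-ward costing: net inpatient days fall, but a small
        increase in the expensive ICU makes the hospitalization cost
        DiD positive."""
        udid = pd.Series({"ward_medical": -0.12, "ward_surgical": -0.08, "icu": 0.06})
        uc = unit_cost_frame(
            {"ward_medical": 350.0, "ward_surgical": 358.875, "icu": 1500.0}
        )
        table = cost_did(udid, uc, 0.0, IndirectRows(0.0, 0.0))
        hosp = table.detail[table.detail["group"] == "hospitalization"]
        assert hosp["utilization_did"].sum() == pytest.approx(-0.14)
        assert hosp["cost_did"].sum() == pytest.approx(19.29)

    def test_missing_unit_cost_is_configuration_error(self):
        udid = pd.Series({"ed": 1.0})
        with pytest.raises(ConfigurationError, match="unit cost"):
            cost_did(udid, unit_cost_frame({}), 0.0, IndirectRows(0.0, 0.0))

    def test_fixture_cost_rows_and_total(self, fixture_results):
        detail = fixture_results.did_table.detail
        assert detail.loc["ed", "cost_did"] == pytest.approx(-83.77, abs=1e-6)
        assert detail.loc["ambulatory", "cost_did"] == pytest.approx(-38.38, abs=1e-6)
        assert detail.loc["surgery", "cost_did"] == pytest.approx(-12.92, abs=1e-6)
        hosp = detail[detail["group"] == "hospitalization"]["cost_did"].sum()
        assert hosp == pytest.approx(19.29, abs=1e-6)
        assert detail.loc["intervention", "cost_did"] == pytest.approx(677.43, abs=1e-6)
        assert fixture_results.did_table.total == pytest.approx(594.27, abs=0.02)

    def test_flat_table_total_matches(self, fixture_results):
        frame = fixture_results.did_table.to_frame()
        total_row = frame[frame["category"] == "total"]["cost_did"].iloc[0]
        parts = frame[frame["category"] != "total"]["cost_did"].sum()
        assert total_row == pytest.approx(parts)
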