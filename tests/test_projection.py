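"""The projection engine: unit cost compounding, daily/annual/cumulative savings."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from careproj import (
    CareSettingScenario,
    Schedule,
    hours_saved_per_day,
    project,
    project_year,
    unit_cost,
)


@pytest.mark.parametrize(
    "c0, g, year, expected",
    [
        (500, 0.10, 1, 500.0),
        (500, 0.10, 10, 500 * 1.1**9),  # 1178.9738...
        (1000, 0.0, 7, 1000.0),
    ],
)
def test_unit_cost_compounding(c0, g, year, expected):
    assert unit_cost(c0, g, year) == pytest.approx(expected, rel=1e-12)


def test_unit_cost_rejects_year_below_one():
    with pytest.raises(ValueError):
        unit_cost(500, 0.1, 0)


@settings(deadline=None)
@given(
    c0=st.floats(1e-3, 1e6),
    g=st.floats(-0.5, 0.5),
    year=st.integers(1, 50),
)
def test_unit_cost_equals_iterative_compounding(c0, g, year):
    stepped = c0
    for _ in range(year - 1):
        stepped *= 1.0 + g
    assert unit_cost(c0, g, year) == pytest.approx(stepped, rel=1e-12)


@pytest.mark.parametrize(
    "patients, minutes, expected",
    [
        (20, 10, 20 * 10 / 60),  # 3.333... h/day
        (65, 14, 65 * 14 / 60),  # 15.1667 h/day
        (0, 50, 0.0),
    ],
)
def test_hours_saved_per_day(patients, minutes, expected):
    assert hours_saved_per_day(patients, minutes) == pytest.approx(expected, rel=1e-12)


def _simple_scenario(**overrides):
    base = dict(
        label="s",
        horizon_years=8,
        patients_per_day=Schedule.linear(10, 30),
        hospitals=Schedule.linear(4, 9),
        saved_minutes=Schedule.linear(6, 12),
        unit_cost_year1=200.0,
        cost_growth_rate=0.05,
        days_per_year=365,
    )
    base.update(overrides)
    return CareSettingScenario(**base)


class TestProjectYear:
    def test_daily_saving_year1_diagnosis(self, diagnosis_scenario):
        row = project_year(diagnosis_scenario, 1)
        assert row.saving_per_day_per_hospital == pytest.approx(1666.6667, rel=1e-4)

    def test_daily_saving_year1_treatment(self, treatment_scenario):
        row = project_year(treatment_scenario, 1)
        assert row.saving_per_day_per_hospital == pytest.approx(21666.67, rel=1e-4)

    def test_daily_saving_year10_treatment(self, treatment_scenario):
        row = project_year(treatment_scenario, 10)
        assert row.saving_per_day_per_hospital == pytest.approx(289634.83, rel=1e-4)

    def test_year_out_of_range(self, diagnosis_scenario):
        with pytest.raises(ValueError, match="horizon"):
            project_year(diagnosis_scenario, 11)

    def test_invalid_scenario_rejected(self):
        sc = _simple_scenario(saved_minutes=None)
        with pytest.raises(ValueError, match="invalid scenario"):
            project_year(sc, 1)

    def test_row_internal_consistency(self, treatment_scenario):
        row = project_year(treatment_scenario, 7)
        assert row.hours_saved_per_day_per_hospital == pytest.approx(
            row.patients_per_day * row.minutes_saved_per_patient / 60, rel=1e-12
        )
        assert row.saving_per_day_per_hospital == pytest.approx(
            row.hours_saved_per_day_per_hospital * row.unit_cost, rel=1e-12
        )
        assert row.system_annual_saving == pytest.approx(
            row.saving_per_day_per_hospital * 365 * row.hospitals, rel=1e-12
        )


class TestProjectTable:
    def test_one_row_per_year(self, diagnosis_table):
        assert diagnosis_table.horizon_years == 10
        assert [r.year for r in diagnosis_table.rows] == list(range(1, 11))

    def test_final_year_hours_diagnosis(self, diagnosis_table):
        assert diagnosis_table.row(10).hours_saved_per_day_per_hospital == pytest.approx(
            15.1667, rel=1e-4
        )

    def test_zero_saving_scenario_all_zero(self):
        table = project(_simple_scenario(saved_minutes=Schedule.constant(0)))
        for row in table.rows:
            assert row.saving_per_day_per_hospital == 0
            assert row.cumulative_system_saving == 0

    def test_cumulative_is_running_sum(self, treatment_table):
        running = 0.0
        for row in treatment_table.rows:
            running += row.system_annual_saving
            assert row.cumulative_system_saving == pytest.approx(running, rel=1e-12)

    def test_cumulative_monotone_under_nonnegative_savings(self, diagnosis_table):
        cums = [r.cumulative_system_saving for r in diagnosis_table.rows]
        assert all(b >= a for a, b in zip(cums, cums[1:]))

    def test_csv_json_roundtrip(self, diagnosis_table, tmp_path):
        jpath = tmp_path / "t.json"
        diagnosis_table.to_json(jpath)
        back = type(diagnosis_table).from_json(jpath)
        assert back == diagnosis_table
        cpath = tmp_path / "t.csv"
        diagnosis_table.to_csv(cpath)
        header = cpath.read_text().splitlines()[0]
        assert header.startswith("year,patients_per_day,hospitals")


@settings(deadline=None, max_examples=25)
@given(k=st.floats(1e-3, 1e3))
def test_currency_outputs_linear_in_unit_cost(k):
    """Scaling C0 by k scales every currency column by exactly k."""
    base = project(_simple_scenario())
    scaled = project(_simple_scenario(unit_cost_year1=200.0 * k))
    for rb, rs in zip(base.rows, scaled.rows):
        for field in (
            "saving_per_day_per_hospital",
            "annual_saving_per_hospital",
            "system_annual_saving",
            "cumulative_system_saving",
        ):
            assert getattr(rs, field) == pytest.approx(
                getattr(rb, field) * k, rel=1e-12
            )
        assert rs.hours_saved_per_day_per_hospital == rb.hours_saved_per_day_per_hospital


def test_zero_growth_keeps_cost_to_time_ratio_constant():
    table = project(_simple_scenario(cost_growth_rate=0.0))
    for row in table.rows:
        assert row.saving_per_day_per_hospital / row.hours_saved_per_day_per_hospital == pytest.approx(
            200.0, rel=1e-12
        )
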