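"""The projection engine: per-year time and cost savings for one scenario.

For each year t the engine computes

    T(t)     = P(t) * s(t) / 60          hours saved per day per hospital
    C(t)     = C0 * (1 + g)^(t-1)        unit cost, currency per hour
    S_day(t) = T(t) * C(t)               saving per day per hospital

and annualizes with the scenario's operating days D:

    annual_saving_per_hospital(t) = S_day(t) * D
    system_annual_saving(t)       = S_day(t) * D * H(t)
    cumulative_system_saving(t)   = sum over 1..t of system_annual_saving

All values are kept at full floating-point precision; rounding happens
only when a table is written out for reporting.  Fractional patient and
hospital counts are allowed and read as expected values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import pandas as pd

from .scenario import CareSettingScenario, resolve, saved_minutes_at, validate

__all__ = [
    "YearProjection",
    "ProjectionTable",
    "unit_cost",
    "hours_saved_per_day",
    "project_year",
    "project",
    "PROJECTION_COLUMNS",
]

#: Column order used by the CSV and DataFrame writers.
PROJECTION_COLUMNS = (
    "year",
    "patients_per_day",
    "hospitals",
    "minutes_saved_per_patient",
    "hours_saved_per_day_per_hospital",
    "unit_cost",
    "saving_per_day_per_hospital",
    "annual_saving_per_hospital",
    "system_annual_saving",
    "cumulative_system_saving",
)


@dataclasses.dataclass(frozen=True)
class YearProjection:
    """All projected quantities for a single year."""

    year: int
    patients_per_day: float
    hospitals: float
    minutes_saved_per_patient: float
    hours_saved_per_day_per_hospital: float
    unit_cost: float
    saving_per_day_per_hospital: float
    annual_saving_per_hospital: float
    system_annual_saving: float
    cumulative_system_saving: float


def unit_cost(c0: float, g: float, year: int) -> float:
    """Unit cost in a given year under compound annual growth.

    ``c0 * (1 + g) ** (year - 1)``: the year-1 cost carries no growth.
    """
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    if c0 < 0:
        raise ValueError(f"unit cost must be >= 0, got {c0}")
    return c0 * (1.0 + g) ** (year - 1)


def hours_saved_per_day(patients: float, minutes_saved: float) -> float:
    """Hours of process time saved per day per hospital."""
    return patients * minutes_saved / 60.0


def project_year(
    scenario: CareSettingScenario, year: int, _cumulative_before: float | None = None
) -> YearProjection:
    """Project a single year of a scenario.

    When called standalone the cumulative column holds the single-year
    system saving; :func:`project` threads the running sum through.
    """
    violations = validate(scenario)
    if violations:
        raise ValueError("invalid scenario: " + "; ".join(violations))
    n = scenario.horizon_years
    if not 1 <= year <= n:
        raise ValueError(f"year {year} outside scenario horizon 1..{n}")
    patients = resolve(scenario.patients_per_day, year, n)
    hospitals = resolve(scenario.hospitals, year, n)
    minutes = saved_minutes_at(scenario, year)
    hours = hours_saved_per_day(patients, minutes)
    cost = unit_cost(scenario.unit_cost_year1, scenario.cost_growth_rate, year)
    s_day = hours * cost
    annual = s_day * scenario.days_per_year
    system = annual * hospitals
    cumulative = system if _cumulative_before is None else _cumulative_before + system
    return YearProjection(
        year=year,
        patients_per_day=patients,
        hospitals=hospitals,
        minutes_saved_per_patient=minutes,
        hours_saved_per_day_per_hospital=hours,
        unit_cost=cost,
        saving_per_day_per_hospital=s_day,
        annual_saving_per_hospital=annual,
        system_annual_saving=system,
        cumulative_system_saving=cumulative,
    )


@dataclasses.dataclass(frozen=True)
class ProjectionTable:
    """Per-year projection rows for one scenario, years 1..N without gaps."""

    scenario_label: str
    rows: tuple[YearProjection, ...]

    def __post_init__(self) -> None:
        years = [r.year for r in self.rows]
        if years != list(range(1, len(years) + 1)):
            raise ValueError(f"rows must cover years 1..N without gaps, got {years}")

    @property
    def horizon_years(self) -> int:
        return len(self.rows)

    def row(self, year: int) -> YearProjection:
        if not 1 <= year <= len(self.rows):
            raise ValueError(f"year {year} outside 1..{len(self.rows)}")
        return self.rows[year - 1]

    def to_frame(self) -> pd.DataFrame:
        """The table as a DataFrame with the documented column order."""
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.rows])
        return df[list(PROJECTION_COLUMNS)]

    def to_csv(self, path: Union[str, Path], decimals: int = 2) -> None:
        """Write a report CSV, currency and hours rounded for display."""
        df = self.to_frame().copy()
        for col in PROJECTION_COLUMNS[3:]:
            df[col] = df[col].round(decimals)
        df.to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        """Write full-precision JSON (label plus row records)."""
        payload = {
            "scenario_label": self.scenario_label,
            "rows": [dataclasses.asdict(r) for r in self.rows],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ProjectionTable":
        payload = json.loads(Path(path).read_text())
        rows = tuple(YearProjection(**r) for r in payload["rows"])
        return cls(scenario_label=payload["scenario_label"], rows=rows)


def project(scenario: CareSettingScenario) -> ProjectionTable:
    """Project a scenario over its full horizon.

    Raises ``ValueError`` listing all violations if the scenario is
    invalid.
    """
    violations = validate(scenario)
    if violations:
        raise ValueError("invalid scenario: " + "; ".join(violations))
    rows = []
    cumulative = 0.0
    for year in range(1, scenario.horizon_years + 1):
        row = project_year(scenario, year, _cumulative_before=cumulative)
        cumulative = row.cumulative_system_saving
        rows.append(row)
    return ProjectionTable(scenario_label=scenario.label, rows=tuple(rows))
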