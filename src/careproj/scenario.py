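"""Care-setting scenarios and the yearly schedules that parameterize them.

A scenario describes one care pathway (diagnosis or treatment) over a fixed
horizon of years: how many patients each hospital sees per day, how many
hospitals participate, how many minutes of clinical process time the
AI-assisted pathway saves per patient, and what one hour of that process
time costs.  Each of those quantities is a :class:`Schedule` — a rule
mapping a 1-based year index to a value.

Year indexing is 1-based throughout: "the first year" is ``t = 1`` and
compound growth uses the exponent ``t - 1``, so no growth is applied in
year 1.
"""

from __future__ import annotations

import enum
import math
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "ScheduleKind",
    "Schedule",
    "CareSettingScenario",
    "CareSetting",
    "resolve",
    "saved_minutes_at",
    "validate",
    "baseline_scenario",
]


class ScheduleKind(str, enum.Enum):
    """How a schedule maps the year index to a value."""

    CONSTANT = "constant"
    LINEAR = "linear"
    COMPOUND = "compound"
    EXPLICIT = "explicit"


class Schedule(BaseModel):
    """A rule assigning a value to each year ``1..horizon``.

    Parameters
    ----------
    kind
        One of ``constant``, ``linear``, ``compound``, ``explicit``.
    start_value
        Value in year 1 (all kinds except ``explicit``).
    end_value
        Value in the final year (``linear`` only); intermediate years are
        linearly interpolated.
    rate
        Fractional growth per year (``compound`` only): year *t* resolves
        to ``start_value * (1 + rate) ** (t - 1)``.
    values
        Explicit per-year values (``explicit`` only); the sequence length
        must equal the scenario horizon.
    """

    model_config = ConfigDict(frozen=True)

    kind: ScheduleKind
    start_value: Optional[float] = None
    end_value: Optional[float] = None
    rate: Optional[float] = None
    values: Optional[tuple[float, ...]] = None

    @model_validator(mode="after")
    def _check_fields(self) -> "Schedule":
        k = self.kind
        if k is ScheduleKind.EXPLICIT:
            if self.values is None:
                raise ValueError("explicit schedule requires 'values'")
        else:
            if self.start_value is None:
                raise ValueError(f"{k.value} schedule requires 'start_value'")
            if k is ScheduleKind.LINEAR and self.end_value is None:
                raise ValueError("linear schedule requires 'end_value'")
            if k is ScheduleKind.COMPOUND and self.rate is None:
                raise ValueError("compound schedule requires 'rate'")
        return self

    # Convenience constructors -------------------------------------------

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls(kind=ScheduleKind.CONSTANT, start_value=value)

    @classmethod
    def linear(cls, start: float, end: float) -> "Schedule":
        return cls(kind=ScheduleKind.LINEAR, start_value=start, end_value=end)

    @classmethod
    def compound(cls, start: float, rate: float) -> "Schedule":
        return cls(kind=ScheduleKind.COMPOUND, start_value=start, rate=rate)

    @classmethod
    def explicit(cls, values: Sequence[float]) -> "Schedule":
        return cls(kind=ScheduleKind.EXPLICIT, values=tuple(values))


def resolve(schedule: Schedule, year: int, horizon: int) -> float:
    """Resolve a schedule at a given 1-based year.

    For a linear schedule with horizon 1 the start value is returned.
    Raises ``ValueError`` for a year outside ``1..horizon``, an explicit
    schedule whose length differs from the horizon, or a non-finite result.
    """
    if not 1 <= year <= horizon:
        raise ValueError(f"year {year} outside 1..{horizon}")
    k = schedule.kind
    if k is ScheduleKind.CONSTANT:
        out = schedule.start_value
    elif k is ScheduleKind.LINEAR:
        # endpoints returned exactly; start+(end-start) is not bit-exact
        if horizon == 1 or year == 1:
            out = schedule.start_value
        elif year == horizon:
            out = schedule.end_value
        else:
            span = schedule.end_value - schedule.start_value
            out = schedule.start_value + span * (year - 1) / (horizon - 1)
    elif k is ScheduleKind.COMPOUND:
        out = schedule.start_value * (1.0 + schedule.rate) ** (year - 1)
    else:  # explicit
        if len(schedule.values) != horizon:
            raise ValueError(
                f"explicit schedule has {len(schedule.values)} values, "
                f"horizon is {horizon}"
            )
        out = schedule.values[year - 1]
    out = float(out)
    if not math.isfinite(out):
        raise ValueError(f"schedule resolves to non-finite value at year {year}")
    return out


class CareSetting(str, enum.Enum):
    """The two modelled care pathways."""

    DIAGNOSIS = "diagnosis"
    TREATMENT = "treatment"


class CareSettingScenario(BaseModel):
    """Full parameterization of one care setting over the horizon.

    Per-patient time saving may be given either directly (``saved_minutes``)
    or as the pair ``conventional_minutes`` / ``ai_minutes`` whose
    difference is the saving.  Exactly one of the two forms must be
    supplied; :func:`validate` reports a conflict otherwise.

    Attributes
    ----------
    label : str
        Human-readable name of the care setting.
    horizon_years : int
        Number of projected years N.
    patients_per_day : Schedule
        Patients per day per hospital, P(t).
    hospitals : Schedule
        Number of participating hospitals, H(t).
    conventional_minutes, ai_minutes : Schedule, optional
        Minutes of process time per patient under the conventional and the
        AI-assisted pathway.
    saved_minutes : Schedule, optional
        Minutes saved per patient, s(t), given directly.
    unit_cost_year1 : float
        Cost of one hour of process time in year 1 (currency/hour), C0.
    cost_growth_rate : float
        Fractional annual growth of the unit cost, g; compounded as
        ``C0 * (1 + g) ** (t - 1)``.
    days_per_year : int
        Operating days used to annualize daily savings.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    horizon_years: int
    patients_per_day: Schedule
    hospitals: Schedule
    conventional_minutes: Optional[Schedule] = None
    ai_minutes: Optional[Schedule] = None
    saved_minutes: Optional[Schedule] = None
    unit_cost_year1: float
    cost_growth_rate: float
    days_per_year: int = 365


def saved_minutes_at(scenario: CareSettingScenario, year: int) -> float:
    """Minutes saved per patient at a given year.

    Uses ``saved_minutes`` when present, otherwise the difference between
    conventional and AI minutes.  A negative result is returned as-is;
    :func:`validate` flags it.
    """
    n = scenario.horizon_years
    if scenario.saved_minutes is not None:
        return resolve(scenario.saved_minutes, year, n)
    return resolve(scenario.conventional_minutes, year, n) - resolve(
        scenario.ai_minutes, year, n
    )


def validate(scenario: CareSettingScenario) -> list[str]:
    """Check a scenario against its invariants.

    Returns an empty list for a valid scenario, otherwise one description
    per violation.  Violations are returned, never raised, so that callers
    can report all of them at once.
    """
    out: list[str] = []
    has_direct = scenario.saved_minutes is not None
    has_pair = (
        scenario.conventional_minutes is not None and scenario.ai_minutes is not None
    )
    has_partial_pair = (scenario.conventional_minutes is not None) != (
        scenario.ai_minutes is not None
    )
    if has_direct and (has_pair or has_partial_pair):
        out.append(
            "saved_minutes conflicts with conventional_minutes/ai_minutes: "
            "give either the direct saving or the minute pair, not both"
        )
    elif not has_direct and not has_pair:
        out.append(
            "no time saving specified: give saved_minutes or both "
            "conventional_minutes and ai_minutes"
        )
    if scenario.horizon_years < 1:
        out.append(f"horizon_years must be >= 1, got {scenario.horizon_years}")
    if scenario.unit_cost_year1 < 0:
        out.append(f"unit_cost_year1 must be >= 0, got {scenario.unit_cost_year1}")
    if scenario.days_per_year < 1:
        out.append(f"days_per_year must be >= 1, got {scenario.days_per_year}")
    if out:
        return out  # schedules cannot be resolved meaningfully
    for year in range(1, scenario.horizon_years + 1):
        try:
            s = saved_minutes_at(scenario, year)
        except ValueError as exc:
            out.append(f"year {year}: {exc}")
            continue
        if s < 0:
            out.append(f"year {year}: saved minutes per patient is negative ({s})")
        for name in ("patients_per_day", "hospitals"):
            try:
                resolve(getattr(scenario, name), year, scenario.horizon_years)
            except ValueError as exc:
                out.append(f"{name}, year {year}: {exc}")
    return out


# Calibrated baselines ----------------------------------------------------
#
# The two reference scenarios reproduce the published year-1 and year-10
# endpoints for AI-assisted diagnosis and treatment.  Per-patient minute
# endpoints are calibration constants obtained by dividing the published
# daily hours saved by the published daily patient counts (diagnosis:
# 200 min / 20 patients -> 10, 910 / 65 -> 14; treatment: 1300 / 20 -> 65,
# 7370 / 55 -> 134) and interpolating linearly between, matching the linear
# style of the volume schedules.  The 10%/yr growth assumption applies to
# the hourly unit cost only.

_BASELINES = {
    CareSetting.DIAGNOSIS: dict(
        label="diagnosis",
        horizon_years=10,
        patients_per_day=Schedule.linear(20, 65),
        hospitals=Schedule.linear(20, 38),
        saved_minutes=Schedule.linear(10, 14),
        unit_cost_year1=500.0,
        cost_growth_rate=0.10,
        days_per_year=365,
    ),
    CareSetting.TREATMENT: dict(
        label="treatment",
        horizon_years=10,
        patients_per_day=Schedule.linear(20, 55),
        hospitals=Schedule.linear(15, 21),
        saved_minutes=Schedule.linear(65, 134),
        unit_cost_year1=1000.0,
        cost_growth_rate=0.10,
        days_per_year=365,
    ),
}


def baseline_scenario(setting: CareSetting | str) -> CareSettingScenario:
    """Return the calibrated baseline scenario for a care setting.

    ``setting`` is ``"diagnosis"`` or ``"treatment"`` (or the corresponding
    :class:`CareSetting`).  Raises ``ValueError`` for any other label.
    """
    try:
        setting = CareSetting(setting)
    except ValueError:
        valid = ", ".join(s.value for s in CareSetting)
        raise ValueError(f"unknown care setting {setting!r}; expected one of: {valid}")
    return CareSettingScenario(**_BASELINES[setting])
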