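"""One-way sensitivity sweeps and elasticities over scenario assumptions.

A sweep replaces one scalar field of a scenario (addressed by a dotted
path such as ``cost_growth_rate`` or ``saved_minutes.end_value``) with each
value of a grid, reprojects, and records a named outcome.  The elasticity
is the central-difference estimate of %-change in outcome per %-change in
parameter at the baseline; for the unit cost it is exactly 1 (savings are
linear in C0), and for the growth rate it approaches (N-1)·g/(1+g).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .projection import ProjectionTable, project
from .scenario import CareSettingScenario, Schedule

__all__ = ["SweepResult", "OUTCOMES", "one_way_sweep", "elasticity", "scenario_outcome"]

#: Recognized scalar outcomes of a projection, all taken at the final year.
OUTCOMES = (
    "saving_per_day_final_year",
    "cumulative_system_saving_final_year",
    "hours_saved_final_year",
)


def scenario_outcome(table: ProjectionTable, outcome_name: str) -> float:
    """Extract a named scalar outcome from a projection table."""
    last = table.rows[-1]
    if outcome_name == "saving_per_day_final_year":
        return last.saving_per_day_per_hospital
    if outcome_name == "cumulative_system_saving_final_year":
        return last.cumulative_system_saving
    if outcome_name == "hours_saved_final_year":
        return last.hours_saved_per_day_per_hospital
    raise ValueError(
        f"unknown outcome {outcome_name!r}; expected one of: {', '.join(OUTCOMES)}"
    )


def _get_param(scenario: CareSettingScenario, path: str) -> float:
    parts = path.split(".")
    obj = scenario
    for p in parts:
        if not hasattr(obj, p):
            raise ValueError(f"unknown parameter path {path!r} (no field {p!r})")
        obj = getattr(obj, p)
        if obj is None:
            raise ValueError(f"parameter path {path!r}: field {p!r} is unset")
    if not isinstance(obj, (int, float)) or isinstance(obj, bool):
        raise ValueError(f"parameter path {path!r} does not address a scalar")
    return float(obj)


def _set_param(scenario: CareSettingScenario, path: str, value: float) -> CareSettingScenario:
    parts = path.split(".")
    if len(parts) == 1:
        return scenario.model_copy(update={parts[0]: value})
    if len(parts) == 2:
        sched = getattr(scenario, parts[0])
        if not isinstance(sched, Schedule):
            raise ValueError(f"parameter path {path!r}: {parts[0]!r} is not a schedule")
        new_sched = sched.model_copy(update={parts[1]: value})
        return scenario.model_copy(update={parts[0]: new_sched})
    raise ValueError(f"parameter path {path!r} is too deep")


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Outcome of a one-way sweep.

    ``outcomes`` holds NaN at grid points where the modified scenario was
    invalid; ``errors`` records the violation text per such point.
    ``elasticity`` is NaN when undefined (zero baseline parameter or
    outcome).
    """

    parameter_path: str
    grid: tuple[float, ...]
    outcome_name: str
    outcomes: tuple[float, ...]
    baseline_value: float
    baseline_outcome: float
    elasticity: float
    errors: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.parameter_path: self.grid, self.outcome_name: self.outcomes}
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, allow_nan=True) + "\n"
        )


def one_way_sweep(
    scenario: CareSettingScenario,
    parameter_path: str,
    grid: Sequence[float],
    outcome_name: str,
) -> SweepResult:
    """Sweep one scalar parameter over a grid and record an outcome.

    Grid points that make the scenario invalid yield NaN outcomes with the
    violation recorded, rather than aborting the sweep.
    """
    baseline_value = _get_param(scenario, parameter_path)
    if outcome_name not in OUTCOMES:
        raise ValueError(
            f"unknown outcome {outcome_name!r}; expected one of: {', '.join(OUTCOMES)}"
        )
    baseline_outcome = scenario_outcome(project(scenario), outcome_name)
    outcomes: list[float] = []
    errors: list[str] = []
    for value in grid:
        try:
            modified = _set_param(scenario, parameter_path, float(value))
            outcomes.append(scenario_outcome(project(modified), outcome_name))
        except ValueError as exc:
            outcomes.append(math.nan)
            errors.append(f"{parameter_path}={value}: {exc}")
    try:
        elast = elasticity(scenario, parameter_path, outcome_name)
    except ValueError:
        elast = math.nan
    return SweepResult(
        parameter_path=parameter_path,
        grid=tuple(float(v) for v in grid),
        outcome_name=outcome_name,
        outcomes=tuple(outcomes),
        baseline_value=baseline_value,
        baseline_outcome=baseline_outcome,
        elasticity=elast,
        errors=tuple(errors),
    )


def elasticity(
    scenario: CareSettingScenario,
    parameter_path: str,
    outcome_name: str,
    relative_step: float = 1e-4,
) -> float:
    """Central-difference elasticity of an outcome at the baseline.

    Defined as (%Δoutcome)/(%Δparameter) for a symmetric relative
    perturbation of the parameter.  Raises ``ValueError`` when the baseline
    parameter or outcome is zero (elasticity undefined) or the step is
    outside (0, 0.1].
    """
    if not 0 < relative_step <= 0.1:
        raise ValueError(f"relative_step must be in (0, 0.1], got {relative_step}")
    x0 = _get_param(scenario, parameter_path)
    if x0 == 0:
        raise ValueError(f"elasticity undefined: baseline {parameter_path} is zero")
    y0 = scenario_outcome(project(scenario), outcome_name)
    if y0 == 0:
        raise ValueError(f"elasticity undefined: baseline {outcome_name} is zero")
    h = abs(x0) * relative_step
    y_hi = scenario_outcome(project(_set_param(scenario, parameter_path, x0 + h)), outcome_name)
    y_lo = scenario_outcome(project(_set_param(scenario, parameter_path, x0 - h)), outcome_name)
    return (y_hi - y_lo) / (2 * h) * (x0 / y0)
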