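"""Random but structurally faithful scenarios, plus parameter-recovery oracles.

The published model states only year-1 and year-10 endpoints; its detailed
assumption tables are not available.  This module stands in for them: it
draws scenario endpoints uniformly from user-specified intervals and builds
scenarios with the same structure as the calibrated baselines — linear
patient, hospital and saved-minute schedules, a constant-rate compound
unit cost.  Generation is a deterministic function of the prior and its
integer seed.

``recover_inflation`` is the inverse check: given a projection table it
re-estimates the unit-cost growth rate from the ratio of daily cost to
daily time savings, which on noiseless engine output recovers the input
rate to near machine precision.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .projection import ProjectionTable
from .scenario import CareSettingScenario, Schedule

__all__ = ["ScenarioPrior", "generate_scenario", "generate_suite", "recover_inflation"]

Interval = tuple[float, float]


class ScenarioPrior(BaseModel):
    """Uniform ranges for scenario endpoints and the generator seed.

    Each range is an (lower, upper) interval with nonnegative lower bound.
    Defaults bracket the calibrated diagnosis/treatment baselines, giving
    hospital systems of plausible size.
    """

    model_config = ConfigDict(frozen=True)

    patients_year1_range: Interval = (10.0, 30.0)
    patients_yearN_range: Interval = (30.0, 80.0)
    hospitals_year1_range: Interval = (10.0, 25.0)
    hospitals_yearN_range: Interval = (15.0, 45.0)
    saved_minutes_year1_range: Interval = (5.0, 70.0)
    saved_minutes_yearN_range: Interval = (10.0, 140.0)
    unit_cost_range: Interval = (250.0, 1500.0)
    growth_rate_range: Interval = (0.0, 0.2)
    horizon: int = 10
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScenarioPrior":
        for name in (
            "patients_year1_range",
            "patients_yearN_range",
            "hospitals_year1_range",
            "hospitals_yearN_range",
            "saved_minutes_year1_range",
            "saved_minutes_yearN_range",
            "unit_cost_range",
            "growth_rate_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 0:
                raise ValueError(f"{name}: lower bound must be nonnegative, got {lo}")
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        return self


def _draw_endpoints(rng: np.random.Generator, r1: Interval, rn: Interval) -> tuple[float, float]:
    # Endpoints drawn independently; a decreasing pair is swapped so the
    # schedule stays monotone non-decreasing, like the baseline curves.
    start = rng.uniform(*r1)
    end = rng.uniform(*rn)
    if end < start:
        start, end = end, start
    return start, end


def generate_scenario(prior: ScenarioPrior, seed: int | None = None) -> CareSettingScenario:
    """Draw one scenario from the prior.

    ``seed`` overrides the prior's seed; the result is a deterministic
    function of (prior, seed) and always passes scenario validation.
    """
    if seed is None:
        seed = prior.seed
    rng = np.random.default_rng(seed)
    p1, pn = _draw_endpoints(rng, prior.patients_year1_range, prior.patients_yearN_range)
    h1, hn = _draw_endpoints(rng, prior.hospitals_year1_range, prior.hospitals_yearN_range)
    s1, sn = _draw_endpoints(
        rng, prior.saved_minutes_year1_range, prior.saved_minutes_yearN_range
    )
    return CareSettingScenario(
        label=f"synthetic-{seed}",
        horizon_years=prior.horizon,
        patients_per_day=Schedule.linear(p1, pn),
        hospitals=Schedule.linear(h1, hn),
        saved_minutes=Schedule.linear(s1, sn),
        unit_cost_year1=float(rng.uniform(*prior.unit_cost_range)),
        cost_growth_rate=float(rng.uniform(*prior.growth_rate_range)),
        days_per_year=365,
    )


def generate_suite(prior: ScenarioPrior, n: int) -> list[CareSettingScenario]:
    """Generate ``n`` scenarios from consecutive seeds seed, seed+1, ..."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return [generate_scenario(prior, seed=prior.seed + k) for k in range(n)]


def recover_inflation(table: ProjectionTable) -> float:
    """Re-estimate the unit-cost growth rate from a projection table.

    The per-year ratio of daily cost saving to daily hours saved is the
    unit cost C(t) = C0 (1+g)^(t-1), so the least-squares slope of
    ln C(t) against (t-1), exponentiated, recovers 1+g.  Requires at
    least two years with strictly positive hours and savings.
    """
    pairs = [
        (r.year, r.saving_per_day_per_hospital / r.hours_saved_per_day_per_hospital)
        for r in table.rows
        if r.hours_saved_per_day_per_hospital > 0 and r.saving_per_day_per_hospital > 0
    ]
    if len(pairs) < 2:
        raise ValueError(
            f"need at least 2 years with positive savings to recover the rate, "
            f"got {len(pairs)}"
        )
    t = np.array([y - 1 for y, _ in pairs], dtype=float)
    ratio = np.array([c for _, c in pairs], dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("nonpositive cost/time ratio; cannot take logarithm")
    slope = np.polyfit(t, np.log(ratio), 1)[0]
    return float(math.expm1(slope))
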