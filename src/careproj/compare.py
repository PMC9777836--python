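"""Combine care-setting projections and net them against AI adoption costs.

``combine`` pairs the diagnosis and treatment projections year by year,
reporting the ratio of their daily savings and the combined cumulative
system saving.  ``net_savings`` subtracts a simple AI cost model — a
one-time per-hospital acquisition cost charged in year 1 plus a recurring
per-hospital running cost — and reports the payback year, the first year
at which cumulative net savings are nonnegative.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .projection import ProjectionTable

__all__ = ["ComparisonTable", "AICostModel", "NetSavingsTable", "combine", "net_savings"]


@dataclasses.dataclass(frozen=True)
class ComparisonTable:
    """Year-by-year pairing of two care-setting projections.

    ``treatment_to_diagnosis_ratio`` entries are NaN where the diagnosis
    daily saving is zero (ratio undefined).
    """

    years: tuple[int, ...]
    diagnosis_saving_per_day: tuple[float, ...]
    treatment_saving_per_day: tuple[float, ...]
    treatment_to_diagnosis_ratio: tuple[float, ...]
    combined_cumulative_system_saving: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "diagnosis_saving_per_day": self.diagnosis_saving_per_day,
                "treatment_saving_per_day": self.treatment_saving_per_day,
                "treatment_to_diagnosis_ratio": self.treatment_to_diagnosis_ratio,
                "combined_cumulative_system_saving": self.combined_cumulative_system_saving,
            }
        )

    def to_csv(self, path: Union[str, Path], decimals: int = 2) -> None:
        df = self.to_frame().copy()
        for col in df.columns[1:]:
            df[col] = df[col].round(decimals)
        df.to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, allow_nan=True) + "\n"
        )


def combine(diagnosis: ProjectionTable, treatment: ProjectionTable) -> ComparisonTable:
    """Pair two projections over a common year range.

    Raises ``ValueError`` when the horizons differ.
    """
    if diagnosis.horizon_years != treatment.horizon_years:
        raise ValueError(
            f"year ranges differ: {diagnosis.horizon_years} vs "
            f"{treatment.horizon_years} years"
        )
    years, d_day, t_day, ratio, combined = [], [], [], [], []
    for rd, rt in zip(diagnosis.rows, treatment.rows):
        years.append(rd.year)
        d_day.append(rd.saving_per_day_per_hospital)
        t_day.append(rt.saving_per_day_per_hospital)
        ratio.append(
            rt.saving_per_day_per_hospital / rd.saving_per_day_per_hospital
            if rd.saving_per_day_per_hospital != 0
            else math.nan
        )
        combined.append(rd.cumulative_system_saving + rt.cumulative_system_saving)
    return ComparisonTable(
        years=tuple(years),
        diagnosis_saving_per_day=tuple(d_day),
        treatment_saving_per_day=tuple(t_day),
        treatment_to_diagnosis_ratio=tuple(ratio),
        combined_cumulative_system_saving=tuple(combined),
    )


class AICostModel(BaseModel):
    """Costs of adopting the AI system, per hospital.

    ``capex_per_hospital`` is charged once, in year 1, for the year-1
    hospital count; hospitals joining later are assumed equipped out of
    the recurring ``opex_per_hospital_per_year``.
    """

    model_config = ConfigDict(frozen=True)

    capex_per_hospital: float = 0.0
    opex_per_hospital_per_year: float = 0.0


@dataclasses.dataclass(frozen=True)
class NetSavingsTable:
    """A projection extended with net-of-cost columns and the payback year.

    ``payback_year`` is the first year with cumulative net saving >= 0
    (boundary inclusive), or ``None`` when payback never occurs within the
    horizon.
    """

    projection: ProjectionTable
    annual_ai_cost: tuple[float, ...]
    net_system_annual_saving: tuple[float, ...]
    cumulative_net_system_saving: tuple[float, ...]
    payback_year: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        df = self.projection.to_frame()
        df["annual_ai_cost"] = self.annual_ai_cost
        df["net_system_annual_saving"] = self.net_system_annual_saving
        df["cumulative_net_system_saving"] = self.cumulative_net_system_saving
        return df

    def to_csv(self, path: Union[str, Path], decimals: int = 2) -> None:
        df = self.to_frame().copy()
        for col in df.columns[3:]:
            df[col] = df[col].round(decimals)
        df.to_csv(path, index=False)


def net_savings(table: ProjectionTable, costs: AICostModel) -> NetSavingsTable:
    """Net a projection against an AI cost model.

    Per-year net system saving is the gross system saving minus the
    recurring cost for that year's hospital count, minus — in year 1 only —
    the one-time acquisition cost for the year-1 hospitals.
    """
    if costs.capex_per_hospital < 0 or costs.opex_per_hospital_per_year < 0:
        raise ValueError("cost parameters must be nonnegative")
    annual_cost, net, cum_net = [], [], []
    running = 0.0
    payback: Optional[int] = None
    for row in table.rows:
        cost = costs.opex_per_hospital_per_year * row.hospitals
        if row.year == 1:
            cost += costs.capex_per_hospital * row.hospitals
        n = row.system_annual_saving - cost
        running += n
        annual_cost.append(cost)
        net.append(n)
        cum_net.append(running)
        if payback is None and running >= 0:
            payback = row.year
    return NetSavingsTable(
        projection=table,
        annual_ai_cost=tuple(annual_cost),
        net_system_annual_saving=tuple(net),
        cumulative_net_system_saving=tuple(cum_net),
        payback_year=payback,
    )
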