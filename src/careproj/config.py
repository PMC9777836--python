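"""JSON run configurations: reading, validation, serialization, schema.

A run config holds one or two care-setting scenarios keyed by role
(``diagnosis``, ``treatment``), an optional AI cost model, an output
directory and the decimal places used in report CSVs.  Scenario objects
mirror the scenario types field for field, so configs round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .compare import AICostModel
from .scenario import CareSettingScenario, validate as validate_scenario
from .synthetic import ScenarioPrior

__all__ = ["RunConfig", "ConfigError", "read_config", "write_config", "read_prior",
           "run_config_schema", "baseline_config_path"]


class ConfigError(ValueError):
    """A configuration file that is missing, unparseable, or invalid."""


class RunConfig(BaseModel):
    """Top-level run configuration."""

    model_config = ConfigDict(frozen=True)

    scenarios: dict[str, CareSettingScenario]
    ai_costs: Optional[AICostModel] = None
    output_dir: str = "."
    report_rounding: int = Field(default=2, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.scenarios:
            raise ValueError("at least one scenario is required under 'scenarios'")
        unknown = set(self.scenarios) - {"diagnosis", "treatment"}
        if unknown:
            raise ValueError(
                f"unknown scenario roles {sorted(unknown)}; "
                "expected 'diagnosis' and/or 'treatment'"
            )
        return self


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = "/" + "/".join(str(p) for p in err["loc"])
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def read_config(path: Union[str, Path]) -> RunConfig:
    """Read and validate a JSON run configuration.

    Raises :class:`ConfigError` with JSON-pointer-style locations on
    schema violations, and also when any contained scenario fails the
    scenario-level validation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config is not valid JSON: {exc}") from exc
    try:
        cfg = RunConfig.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(f"config schema violation: {_format_errors(exc)}") from exc
    for role, scenario in cfg.scenarios.items():
        violations = validate_scenario(scenario)
        if violations:
            raise ConfigError(
                f"scenario '{role}' is invalid: " + "; ".join(violations)
            )
    return cfg


def write_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Write a run configuration as JSON (inverse of :func:`read_config`)."""
    Path(path).write_text(
        json.dumps(cfg.model_dump(mode="json", exclude_none=True), indent=2) + "\n"
    )


def read_prior(path: Union[str, Path]) -> ScenarioPrior:
    """Read a scenario-generator prior from JSON."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"prior file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"prior is not valid JSON: {exc}") from exc
    try:
        return ScenarioPrior.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(f"prior schema violation: {_format_errors(exc)}") from exc


def run_config_schema() -> dict:
    """The JSON Schema that run configurations must satisfy."""
    return RunConfig.model_json_schema()


def baseline_config_path() -> Path:
    """Path of the packaged config holding both calibrated baselines."""
    return Path(__file__).parent / "data" / "baselines.json"
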