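"""Scenario runner: declarative overrides on a base model specification.

A scenario is data, not code: a name plus a set of (dotted path, value)
overrides — e.g. alternative 90-day distributions, a different discount
rate, a shorter horizon, or an older cohort — applied to a deep copy of the
base spec and re-validated.  The runner emits a results table with one
row pair (comparator, intervention) per scenario.
"""

from __future__ import annotations

import logging
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import economics, paths
from .config_io import ConfigError, DiscountSpec, ModelSpec, validate_model

__all__ = ["ScenarioSpec", "apply_scenario", "run_scenario_table"]

logger = logging.getLogger(__name__)


class ScenarioSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    overrides: dict[str, Any] = Field(default_factory=dict)
    horizon: Optional[int] = None
    discount: Optional[DiscountSpec] = None


def apply_scenario(base: ModelSpec, scenario: ScenarioSpec) -> ModelSpec:
    """Apply a scenario's overrides to a deep copy of the base spec.

    The base spec is never mutated; an unresolvable override path raises a
    ConfigError naming it, and the overridden spec must re-validate.
    """
    spec = base.model_copy(deep=True)
    for path, value in scenario.overrides.items():
        try:
            paths.set_value(spec, path, value)
        except ConfigError as exc:
            raise ConfigError(f"scenario {scenario.name!r}: {exc}") from exc
    if scenario.horizon is not None:
        spec.horizon = scenario.horizon
    if scenario.discount is not None:
        spec.discount = scenario.discount.model_copy()
    violations = validate_model(spec)
    if violations:
        raise ConfigError(
            f"scenario {scenario.name!r} produced an invalid model:\n  "
            + "\n  ".join(violations)
        )
    return spec


def run_scenario_table(
    base: ModelSpec, scenarios: list[ScenarioSpec]
) -> pd.DataFrame:
    """Base case plus every scenario as a published-results-style table."""
    frames = []
    for label, spec in [("base case", base)] + [
        (sc.name, apply_scenario(base, sc)) for sc in scenarios
    ]:
        try:
            result = economics.compare_arms(spec)
        except Exception as exc:
            raise ConfigError(f"scenario {label!r} failed: {exc}") from exc
        frame = result.as_dataframe()
        frame.insert(0, "scenario", label)
        frames.append(frame)
        logger.info("scenario %s: %s", label, result.icer)
    return pd.concat(frames, ignore_index=True)
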