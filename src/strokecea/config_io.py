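"""Data model, configuration I/O and validation.

The model state space is the five-state collapse of the modified Rankin
Scale used throughout the package: excellent outcome (mRS 0-1), moderate
outcome (mRS 2-3), mRS 4, mRS 5 and death.  A complete model run is
parameterised by a single :class:`ModelSpec`: two treatment arms (the
comparator listed first), the 90-day-to-1-year and annual transition
matrices, per-state utilities and annual costs, a background life table,
discounting, the time horizon and the sensitivity-analysis configuration.

Configurations are single YAML documents (``schema_version: 1``).
Probabilities are always decimals (0.369, never 36.9): any value above 1 in
a probability slot is rejected, which prevents silent percent/proportion
mix-ups.  Rows of probability vectors that sum to within 1e-6 of 1 (table
rounding) are renormalised once on input; after that every vector must sum
to 1 within 1e-9.

Structural/type errors are raised while parsing; domain invariants are
checked by :func:`validate_model`, which *returns* a list of human-readable
violations so invalid objects can be constructed and inspected in tests.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from typing import Any, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "STATES",
    "N_STATES",
    "DEAD",
    "SCHEMA_VERSION",
    "ConfigError",
    "StateDistribution",
    "TransitionMatrix",
    "PatientProfile",
    "VialSpec",
    "ArmSpec",
    "UtilitySet",
    "AnnualCostSet",
    "DiscountSpec",
    "LifeTable",
    "EconomicsConfig",
    "OWSAParameter",
    "OWSAConfig",
    "DistributionSpec",
    "PSAConfig",
    "ModelSpec",
    "parse_model_config",
    "serialize_model_config",
    "validate_model",
]

logger = logging.getLogger(__name__)

#: Ordered health-state labels; death is always last (absorbing).
STATES: tuple[str, ...] = ("mRS01", "mRS23", "mRS4", "mRS5", "dead")
N_STATES = len(STATES)
DEAD = N_STATES - 1

SCHEMA_VERSION = 1

#: Tolerance for a probability vector to be accepted as stochastic.
ROW_TOL = 1e-9
#: Rows off by no more than this (published-table rounding) are renormalised.
RENORM_TOL = 1e-6


class ConfigError(ValueError):
    """A configuration document violates the schema or an invariant."""


def _coerce_probs(value: Any, where: str = "probability vector") -> list[float]:
    """Coerce a mapping or sequence into an ordered 5-probability list.

    Applies the single renormalisation pass for rows whose sum is within
    ``RENORM_TOL`` (but not already within ``ROW_TOL``) of 1.
    """
    if isinstance(value, dict):
        missing = [s for s in STATES if s not in value]
        if missing:
            raise ValueError(f"{where}: missing states {missing}")
        extra = [k for k in value if k not in STATES]
        if extra:
            raise ValueError(f"{where}: unknown states {extra}")
        value = [value[s] for s in STATES]
    probs = [float(v) for v in value]
    if len(probs) != N_STATES:
        raise ValueError(f"{where}: expected {N_STATES} entries, got {len(probs)}")
    total = sum(probs)
    if total > 0 and ROW_TOL < abs(total - 1.0) <= RENORM_TOL:
        probs = [p / total for p in probs]
    return probs


class StateDistribution(BaseModel):
    """Probability vector over the five health states at one time point."""

    model_config = ConfigDict(extra="forbid")

    probs: list[float]

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        if isinstance(data, StateDistribution):
            return data
        if isinstance(data, dict) and "probs" not in data:
            return {"probs": _coerce_probs(data)}
        if isinstance(data, (list, tuple, np.ndarray)):
            return {"probs": _coerce_probs(data)}
        if isinstance(data, dict):
            return {"probs": _coerce_probs(data["probs"])}
        return data

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(STATES, self.probs))

    def __getitem__(self, state: str) -> float:
        return self.probs[STATES.index(state)]

    def violations(self, name: str = "distribution") -> list[str]:
        out: list[str] = []
        for s, p in zip(STATES, self.probs):
            if p < 0.0:
                out.append(f"{name}[{s}]: negative probability {p}")
            if p > 1.0:
                out.append(
                    f"{name}[{s}]: probability {p} > 1 (probabilities must be "
                    "decimals, not percentages)"
                )
        total = sum(self.probs)
        if abs(total - 1.0) > ROW_TOL:
            out.append(f"{name}: entries sum to {total!r}, not 1 within {ROW_TOL}")
        return out


class TransitionMatrix(BaseModel):
    """Row-stochastic 5x5 per-interval transition matrix, death absorbing."""

    model_config = ConfigDict(extra="forbid")

    rows: list[list[float]]

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        if isinstance(data, TransitionMatrix):
            return data
        raw = data["rows"] if isinstance(data, dict) and "rows" in data else data
        if isinstance(raw, dict):
            missing = [s for s in STATES if s not in raw]
            if missing:
                raise ValueError(f"transition matrix: missing rows {missing}")
            raw = [raw[s] for s in STATES]
        if not isinstance(raw, (list, tuple, np.ndarray)) or len(raw) != N_STATES:
            raise ValueError(f"transition matrix: expected {N_STATES} rows")
        rows = [
            _coerce_probs(r, where=f"transition row {STATES[i]}")
            for i, r in enumerate(raw)
        ]
        return {"rows": rows}

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rows, dtype=float)

    def as_mapping(self) -> dict[str, dict[str, float]]:
        return {s: dict(zip(STATES, row)) for s, row in zip(STATES, self.rows)}

    def violations(self, name: str = "matrix") -> list[str]:
        out: list[str] = []
        for s, row in zip(STATES, self.rows):
            out.extend(StateDistribution(probs=row).violations(f"{name} row {s}"))
        dead_row = self.rows[DEAD]
        expected = [0.0] * N_STATES
        expected[DEAD] = 1.0
        if any(abs(a - b) > ROW_TOL for a, b in zip(dead_row, expected)):
            out.append(f"{name} row dead: death must be absorbing (0,0,0,0,1), got {dead_row}")
        return out


class PatientProfile(BaseModel):
    """Modelled cohort entry profile (drives dosing and life-table lookup)."""

    model_config = ConfigDict(extra="forbid")

    start_age: float = Field(gt=0, description="age at stroke, years")
    weight: float = Field(gt=0, description="body weight, kg")


class VialSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    size_mg: float = Field(gt=0)
    price: float = Field(ge=0, description="euro per vial")


class ArmSpec(BaseModel):
    """One treatment strategy: thrombolytic drug, costs and 90-day outcomes.

    ``dist90_no_evt`` is the 90-day mRS distribution without thrombectomy;
    ``dist90_with_evt`` the distribution when EVT is performed.  A YAML key
    ``dist90`` is shorthand for "one distribution for everyone" and fills
    ``dist90_no_evt`` leaving ``dist90_with_evt`` unset (treated as equal).
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    drug: str = ""
    dose_per_kg: float = Field(default=0.9, gt=0, description="mg per kg")
    drug_cost_mode: Literal["flat", "per_vial"] = "flat"
    flat_drug_cost: Optional[float] = None
    vial_catalog: list[VialSpec] = Field(default_factory=list)
    admin_cost: float = 0.0
    evt_eligible_fraction: float = 0.0
    evt_forgone_fraction: float = 0.0
    evt_cost: float = 0.0
    dist90_with_evt: Optional[StateDistribution] = None
    dist90_no_evt: StateDistribution

    @model_validator(mode="before")
    @classmethod
    def _dist90_shorthand(cls, data: Any) -> Any:
        if isinstance(data, dict) and "dist90" in data:
            data = dict(data)
            data["dist90_no_evt"] = data.pop("dist90")
        return data

    @property
    def dist90_with_evt_effective(self) -> StateDistribution:
        return self.dist90_with_evt if self.dist90_with_evt is not None else self.dist90_no_evt

    def violations(self) -> list[str]:
        name = f"arm {self.name}"
        out: list[str] = []
        for field in ("evt_eligible_fraction", "evt_forgone_fraction"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                out.append(f"{name}.{field}: fraction {v} outside [0, 1]")
        for field in ("admin_cost", "evt_cost"):
            if getattr(self, field) < 0:
                out.append(f"{name}.{field}: cost must be non-negative")
        if self.drug_cost_mode == "flat":
            if self.flat_drug_cost is None:
                out.append(f"{name}.flat_drug_cost: required in flat drug_cost_mode")
            elif self.flat_drug_cost < 0:
                out.append(f"{name}.flat_drug_cost: cost must be non-negative")
        else:
            if not self.vial_catalog:
                out.append(f"{name}.vial_catalog: required in per_vial drug_cost_mode")
        out.extend(self.dist90_no_evt.violations(f"{name}.dist90_no_evt"))
        if self.dist90_with_evt is not None:
            out.extend(self.dist90_with_evt.violations(f"{name}.dist90_with_evt"))
        if self.evt_eligible_fraction == 0.0 and self.dist90_with_evt is not None:
            a = self.dist90_with_evt.as_array()
            b = self.dist90_no_evt.as_array()
            if np.abs(a - b).max() > ROW_TOL:
                out.append(
                    f"{name}: with evt_eligible_fraction = 0 the two 90-day "
                    "distributions must coincide"
                )
        return out


class UtilitySet(BaseModel):
    """QALY weight per health state; death is anchored at exactly 0."""

    model_config = ConfigDict(extra="forbid")

    values: list[float]

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        return _coerce_state_values(data)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(STATES, self.values))

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.values[DEAD] != 0.0:
            out.append(f"utilities[dead]: must be exactly 0, got {self.values[DEAD]}")
        for s, u in zip(STATES[:DEAD], self.values[:DEAD]):
            if not -1.0 <= u <= 1.0:
                out.append(f"utilities[{s}]: {u} outside [-1, 1]")
        return out


class AnnualCostSet(BaseModel):
    """Annual post-stroke healthcare cost (euro/year) per health state."""

    model_config = ConfigDict(extra="forbid")

    values: list[float]

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        return _coerce_state_values(data)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(STATES, self.values))

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.values[DEAD] != 0.0:
            out.append(f"annual_costs[dead]: must be exactly 0, got {self.values[DEAD]}")
        for s, c in zip(STATES[:DEAD], self.values[:DEAD]):
            if c < 0.0:
                out.append(f"annual_costs[{s}]: cost must be non-negative, got {c}")
        return out


def _coerce_state_values(data: Any) -> Any:
    if isinstance(data, BaseModel):
        return data
    raw = data["values"] if isinstance(data, dict) and "values" in data else data
    if isinstance(raw, dict):
        missing = [s for s in STATES if s not in raw]
        if missing:
            raise ValueError(f"per-state values: missing states {missing}")
        raw = [raw[s] for s in STATES]
    vals = [float(v) for v in raw]
    if len(vals) != N_STATES:
        raise ValueError(f"per-state values: expected {N_STATES} entries, got {len(vals)}")
    return {"values": vals}


class DiscountSpec(BaseModel):
    """Annual discount rates (Dutch guideline base case: 4% costs, 1.5% effects).

    ``convention`` fixes when the interval ending at year t is discounted:
    ``start_of_interval`` leaves year-1 accruals undiscounted and discounts
    the interval ending at year t (t >= 2) at exponent t - 1;
    ``end_of_interval`` shifts every exponent one year later.
    """

    model_config = ConfigDict(extra="forbid")

    cost_rate: float = 0.04
    effect_rate: float = 0.015
    convention: Literal["start_of_interval", "end_of_interval"] = "start_of_interval"

    def violations(self) -> list[str]:
        out: list[str] = []
        for field in ("cost_rate", "effect_rate"):
            r = getattr(self, field)
            if not 0.0 <= r < 1.0:
                out.append(f"discount.{field}: rate {r} outside [0, 1)")
        return out


class LifeTable(BaseModel):
    """Age -> annual all-cause death probability for the general population."""

    model_config = ConfigDict(extra="forbid")

    qx: dict[int, float]

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        if isinstance(data, LifeTable):
            return data
        raw = data["qx"] if isinstance(data, dict) and "qx" in data else data
        return {"qx": {int(k): float(v) for k, v in dict(raw).items()}}

    def annual_death_probability(self, age: float) -> float:
        """Annual death probability at `age`.

        Ages beyond the last tabulated age return the last tabulated value;
        ages below the first tabulated age are a configuration error.
        """
        ages = sorted(self.qx)
        if not ages:
            raise ConfigError("life_table: empty table")
        a = int(np.floor(age))
        if a < ages[0]:
            raise ConfigError(
                f"life_table: age {age} below first tabulated age {ages[0]}"
            )
        if a in self.qx:
            return self.qx[a]
        # fall back to the nearest tabulated age below (sparse tables)
        idx = bisect_right(ages, a) - 1
        return self.qx[ages[idx]]

    def violations(self) -> list[str]:
        out: list[str] = []
        for age, q in self.qx.items():
            if not 0.0 <= q <= 1.0:
                out.append(f"life_table[{age}]: probability {q} outside [0, 1]")
        if not self.qx:
            out.append("life_table: must tabulate at least one age")
        return out


def _default_ceac_grid() -> list[float]:
    return [2500.0 * i for i in range(41)]  # 0 .. 100,000 euro/QALY


class EconomicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: willingness-to-pay thresholds (euro/QALY) at which INMB is reported
    thresholds: list[float] = Field(default_factory=lambda: [50_000.0, 80_000.0])
    #: threshold grid for the cost-effectiveness acceptability curve
    ceac_grid: list[float] = Field(default_factory=_default_ceac_grid)

    def violations(self) -> list[str]:
        out: list[str] = []
        for t in self.thresholds:
            if t <= 0:
                out.append(f"economics.thresholds: threshold {t} must be > 0")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            out.append("economics.thresholds: must be strictly increasing")
        return out


class OWSAParameter(BaseModel):
    """One tornado bar: an id plus the parameter path(s) varied together."""

    model_config = ConfigDict(extra="forbid")

    id: str
    targets: list[str]

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        if isinstance(data, str):
            return {"id": data, "targets": [data]}
        if isinstance(data, dict) and "targets" not in data and "id" in data:
            return {"id": data["id"], "targets": [data["id"]]}
        return data


class OWSAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: relative one-way perturbation (0.20 = +-20%)
    perturbation: float = 0.20
    parameters: list[OWSAParameter] = Field(default_factory=list)

    def violations(self) -> list[str]:
        if not 0.0 < self.perturbation < 1.0:
            return [f"owsa.perturbation: {self.perturbation} outside (0, 1)"]
        return []


class DistributionSpec(BaseModel):
    """Sampling distribution for one parameter (or probability vector).

    ``mean``/``se`` default to the base-case value and to (0.2 x mean)/1.96
    — the one-way +-20% range read as a 95% CI — so OWSA and PSA ranges stay
    coherent when no standard error is published.  Dirichlet concentrations
    default to mean x ``ess`` (effective sample size, default 100).
    """

    model_config = ConfigDict(extra="forbid")

    target: str
    kind: Literal["fixed", "beta", "gamma", "dirichlet"]
    mean: Optional[float] = None
    se: Optional[float] = None
    concentration: Optional[list[float]] = None
    ess: float = 100.0

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.ess <= 0:
            out.append(f"psa distribution {self.target}: ess must be > 0")
        if self.se is not None and self.se <= 0:
            out.append(f"psa distribution {self.target}: se must be > 0")
        return out


class PSAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = 10_000
    seed: int = 20_230_519
    distributions: list[DistributionSpec] = Field(default_factory=list)

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.n < 1:
            out.append(f"psa.n: iteration count {self.n} must be >= 1")
        targets = [d.target for d in self.distributions]
        dupes = {t for t in targets if targets.count(t) > 1}
        if dupes:
            out.append(f"psa.distributions: duplicate targets {sorted(dupes)}")
        for d in self.distributions:
            out.extend(d.violations())
        return out


class ModelSpec(BaseModel):
    """Complete parameterisation of one two-arm comparison."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    description: str = ""
    arms: list[ArmSpec]
    t_90to1: TransitionMatrix
    t_annual: TransitionMatrix
    utilities: UtilitySet
    annual_costs: AnnualCostSet
    acute_phase_duration: float = 0.25
    horizon: int = 10
    patient: PatientProfile
    life_table: LifeTable
    discount: DiscountSpec = Field(default_factory=DiscountSpec)
    economics: EconomicsConfig = Field(default_factory=EconomicsConfig)
    owsa: OWSAConfig = Field(default_factory=OWSAConfig)
    psa: PSAConfig = Field(default_factory=PSAConfig)
    #: provenance tag per parameter path: "paper-text" | "assumption"
    provenance: dict[str, str] = Field(default_factory=dict)

    @property
    def comparator(self) -> ArmSpec:
        return self.arms[0]

    @property
    def intervention(self) -> ArmSpec:
        return self.arms[1]

    def arm_by_name(self, name: str) -> ArmSpec:
        for arm in self.arms:
            if arm.name == name:
                return arm
        raise KeyError(f"no arm named {name!r}")


def validate_model(spec: ModelSpec) -> list[str]:
    """Check every domain invariant; return human-readable violations.

    An empty list means the spec is internally consistent.  Violations are
    returned, never raised, so partially-invalid specs can be inspected.
    """
    out: list[str] = []
    if len(spec.arms) != 2:
        out.append(f"arms: exactly two arms required (comparator first), got {len(spec.arms)}")
    names = [a.name for a in spec.arms]
    if len(set(names)) != len(names):
        out.append(f"arms: names must be unique, got {names}")
    for arm in spec.arms:
        out.extend(arm.violations())
    out.extend(spec.t_90to1.violations("t_90to1"))
    out.extend(spec.t_annual.violations("t_annual"))
    out.extend(spec.utilities.violations())
    out.extend(spec.annual_costs.violations())
    out.extend(spec.discount.violations())
    out.extend(spec.life_table.violations())
    out.extend(spec.economics.violations())
    out.extend(spec.owsa.violations())
    out.extend(spec.psa.violations())
    if spec.horizon < 1:
        out.append(f"horizon: must be >= 1 year, got {spec.horizon}")
    if spec.acute_phase_duration <= 0 or spec.acute_phase_duration >= 1:
        out.append(
            f"acute_phase_duration: {spec.acute_phase_duration} outside (0, 1) years"
        )
    return out


def parse_model_config(text: str) -> ModelSpec:
    """Parse and fully validate a YAML model configuration document."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml's message suffices
        raise ConfigError(f"not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("configuration document must be a mapping")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version: unsupported version {version!r}")
    try:
        spec = ModelSpec.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"configuration rejected: {exc}") from exc
    violations = validate_model(spec)
    if violations:
        raise ConfigError(
            "configuration violates model invariants:\n  " + "\n  ".join(violations)
        )
    logger.info("parsed model config: %s (horizon %d y)", spec.description or "<unnamed>", spec.horizon)
    return spec


def _spec_to_document(spec: ModelSpec) -> dict[str, Any]:
    doc = spec.model_dump(exclude_none=True)
    for arm in doc["arms"]:
        for key in ("dist90_no_evt", "dist90_with_evt"):
            if key in arm:
                arm[key] = dict(zip(STATES, arm[key]["probs"]))
    for key in ("t_90to1", "t_annual"):
        doc[key] = {s: dict(zip(STATES, row)) for s, row in zip(STATES, doc[key]["rows"])}
    for key in ("utilities", "annual_costs"):
        doc[key] = dict(zip(STATES, doc[key]["values"]))
    return doc


def serialize_model_config(spec: ModelSpec) -> str:
    """Render a ModelSpec back to YAML; parse(serialize(s)) round-trips."""
    return yaml.safe_dump(_spec_to_document(spec), sort_keys=False, width=100)
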