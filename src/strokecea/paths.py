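"""Dotted-path addressing of model parameters.

Sensitivity sweeps, probabilistic draws and scenario overrides all refer to
parameters by dotted path into the :class:`~strokecea.config_io.ModelSpec`
tree.  Supported forms:

``horizon``, ``acute_phase_duration``, ``patient.start_age``,
``discount.cost_rate`` ...
    plain scalar attributes reached by attribute walk;

``utilities.<state>`` / ``annual_costs.<state>``
    one per-state value;

``arms.<name-or-index>.<field>``
    a scalar arm field (``flat_drug_cost``, ``admin_cost``, ``evt_cost``,
    ``evt_eligible_fraction``, ``evt_forgone_fraction``, ``dose_per_kg``);

``arms.<arm>.dist90[.<state>]``
    the arm's 90-day distribution (or one component of it).  The alias
    ``dist90`` binds ``dist90_no_evt`` and, when present, ``dist90_with_evt``
    together; ``dist90_no_evt`` / ``dist90_with_evt`` address one branch;

``t_90to1.<row-state>[.<col-state>]`` / ``t_annual....``
    a transition-matrix row or single transition probability.

A path resolves to one or more *bindings*; perturbing a probability
component renormalises the rest of its vector so it stays on the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Optional

from .config_io import STATES, ConfigError, ModelSpec, StateDistribution

__all__ = ["Binding", "resolve", "get_values", "set_value"]

#: binding kinds
SCALAR = "scalar"
UTILITY = "utility_component"
PROB_COMPONENT = "prob_component"
PROB_VECTOR = "prob_vector"

_ARM_SCALARS = (
    "flat_drug_cost",
    "admin_cost",
    "evt_cost",
    "evt_eligible_fraction",
    "evt_forgone_fraction",
    "dose_per_kg",
)


@dataclass
class Binding:
    """One addressable parameter slot inside a ModelSpec."""

    path: str
    kind: str
    get: Callable[[], Any]
    set: Callable[[Any], None]

    def set_renormalized(self, new_value: float) -> None:
        """Set a probability component, rescaling the rest of its vector.

        c -> c' with every other component scaled by (1 - c')/(1 - c);
        impossible when c = 1 (nothing left to rescale).
        """
        if self.kind != PROB_COMPONENT:
            raise ConfigError(f"{self.path}: not a probability-vector component")
        self._renorm(new_value)

    _renorm: Callable[[float], None] = None  # type: ignore[assignment]


def _state_index(token: str, path: str) -> int:
    if token not in STATES:
        raise ConfigError(f"{path}: unknown state {token!r} (expected one of {STATES})")
    return STATES.index(token)


def _list_component_binding(path: str, kind: str, owner: Any, attr: str, idx: int) -> Binding:
    def get() -> float:
        return getattr(owner, attr)[idx]

    def set_(value: Any) -> None:
        vals = list(getattr(owner, attr))
        vals[idx] = float(value)
        setattr(owner, attr, vals)

    def renorm(new_c: float) -> None:
        vals = list(getattr(owner, attr))
        c = vals[idx]
        if c >= 1.0:
            raise ConfigError(
                f"{path}: cannot renormalise around a component equal to 1"
            )
        scale = (1.0 - new_c) / (1.0 - c)
        vals = [v * scale for v in vals]
        vals[idx] = new_c
        setattr(owner, attr, vals)

    b = Binding(path=path, kind=kind, get=get, set=set_)
    b._renorm = renorm
    return b


def _vector_binding(path: str, dist: StateDistribution) -> Binding:
    def get() -> list[float]:
        return list(dist.probs)

    def set_(value: Any) -> None:
        coerced = StateDistribution.model_validate(value)
        dist.probs = list(coerced.probs)

    return Binding(path=path, kind=PROB_VECTOR, get=get, set=set_)


def _matrix_row_component(path: str, matrix: Any, row: int, col: int) -> Binding:
    def get() -> float:
        return matrix.rows[row][col]

    def set_(value: Any) -> None:
        rows = [list(r) for r in matrix.rows]
        rows[row][col] = float(value)
        matrix.rows = rows

    def renorm(new_c: float) -> None:
        rows = [list(r) for r in matrix.rows]
        c = rows[row][col]
        if c >= 1.0:
            raise ConfigError(f"{path}: cannot renormalise around a component equal to 1")
        scale = (1.0 - new_c) / (1.0 - c)
        rows[row] = [v * scale for v in rows[row]]
        rows[row][col] = new_c
        matrix.rows = rows

    b = Binding(path=path, kind=PROB_COMPONENT, get=get, set=set_)
    b._renorm = renorm
    return b


def _scalar_binding(path: str, owner: Any, attr: str, kind: str = SCALAR) -> Binding:
    if not hasattr(owner, attr):
        raise ConfigError(f"{path}: unknown parameter")
    current = getattr(owner, attr)
    if current is not None and not isinstance(current, (int, float)):
        raise ConfigError(f"{path}: not a scalar parameter ({type(current).__name__})")

    def get() -> float:
        return getattr(owner, attr)

    def set_(value: Any) -> None:
        setattr(owner, attr, value)

    return Binding(path=path, kind=kind, get=get, set=set_)


def _resolve_dist_tokens(path: str, arm: Any, tokens: list[str]) -> list[Binding]:
    head, rest = tokens[0], tokens[1:]
    if head == "dist90":
        dists = [arm.dist90_no_evt]
        if arm.dist90_with_evt is not None:
            dists.append(arm.dist90_with_evt)
    elif head == "dist90_no_evt":
        dists = [arm.dist90_no_evt]
    else:  # dist90_with_evt
        if arm.dist90_with_evt is None:
            raise ConfigError(f"{path}: arm {arm.name} has no separate EVT distribution")
        dists = [arm.dist90_with_evt]
    if not rest:
        return [_vector_binding(path, d) for d in dists]
    if len(rest) != 1:
        raise ConfigError(f"{path}: trailing tokens after state name")
    idx = _state_index(rest[0], path)
    return [
        _list_component_binding(path, PROB_COMPONENT, d, "probs", idx) for d in dists
    ]


def resolve(spec: ModelSpec, path: str) -> list[Binding]:
    """Resolve a dotted path to its binding(s); raise ConfigError if unknown."""
    tokens = path.split(".")
    if not tokens or not tokens[0]:
        raise ConfigError(f"{path!r}: empty parameter path")
    head = tokens[0]

    if head == "arms":
        if len(tokens) < 3:
            raise ConfigError(f"{path}: expected arms.<arm>.<field>")
        key = tokens[1]
        try:
            arm = spec.arms[int(key)] if key.lstrip("-").isdigit() else spec.arm_by_name(key)
        except (KeyError, IndexError) as exc:
            raise ConfigError(f"{path}: no arm {key!r}") from exc
        sub = tokens[2]
        if sub in ("dist90", "dist90_no_evt", "dist90_with_evt"):
            return _resolve_dist_tokens(path, arm, tokens[2:])
        if len(tokens) != 3 or sub not in _ARM_SCALARS:
            raise ConfigError(f"{path}: unknown arm parameter {sub!r}")
        return [_scalar_binding(path, arm, sub)]

    if head in ("utilities", "annual_costs"):
        if len(tokens) != 2:
            raise ConfigError(f"{path}: expected {head}.<state>")
        idx = _state_index(tokens[1], path)
        owner = spec.utilities if head == "utilities" else spec.annual_costs
        kind = UTILITY if head == "utilities" else SCALAR
        return [_list_component_binding(path, kind, owner, "values", idx)]

    if head in ("t_90to1", "t_annual"):
        matrix = getattr(spec, head)
        if len(tokens) == 2:
            row = _state_index(tokens[1], path)
            dist = StateDistribution(probs=matrix.rows[row])

            def set_row(value: Any, row: int = row) -> None:
                coerced = StateDistribution.model_validate(value)
                rows = [list(r) for r in matrix.rows]
                rows[row] = list(coerced.probs)
                matrix.rows = rows

            return [
                Binding(
                    path=path,
                    kind=PROB_VECTOR,
                    get=lambda row=row: list(matrix.rows[row]),
                    set=set_row,
                )
            ]
        if len(tokens) == 3:
            row = _state_index(tokens[1], path)
            col = _state_index(tokens[2], path)
            return [_matrix_row_component(path, matrix, row, col)]
        raise ConfigError(f"{path}: expected {head}.<row-state>[.<col-state>]")

    # generic attribute walk for everything else
    owner: Any = spec
    for token in tokens[:-1]:
        if not hasattr(owner, token):
            raise ConfigError(f"{path}: unknown parameter")
        owner = getattr(owner, token)
    return [_scalar_binding(path, owner, tokens[-1])]


def get_values(spec: ModelSpec, path: str) -> list[Any]:
    return [b.get() for b in resolve(spec, path)]


def set_value(spec: ModelSpec, path: str, value: Any) -> None:
    """Assign `value` at `path` (all bindings of an alias receive it)."""
    for b in resolve(spec, path):
        b.set(value)
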