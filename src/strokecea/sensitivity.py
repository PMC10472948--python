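"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-evaluates the full comparison with a single
parameter (or grouped set of parameters) moved to +-20% of its base value;
bar endpoints are genuine model runs, never linear approximations.

Probabilistic sensitivity analysis draws every uncertain parameter from its
configured distribution — beta for utilities and single probabilities,
gamma for costs (both by method of moments from mean and standard error),
Dirichlet for whole probability vectors — and re-evaluates the comparison
per draw.  Each draw uses an independent substream seeded as
``default_rng([root_seed, draw_index])``, so enlarging n never reshuffles
earlier draws and a fixed seed reproduces every draw bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics, paths
from .config_io import (
    ConfigError,
    DistributionSpec,
    ModelSpec,
    validate_model,
)

__all__ = [
    "perturb_parameter",
    "TornadoRow",
    "one_way_tornado",
    "beta_from_moments",
    "gamma_from_moments",
    "sample_parameter_set",
    "PSAResult",
    "run_psa",
    "CEACCurve",
    "ceac",
]

logger = logging.getLogger(__name__)

#: default PSA standard error when only a point estimate is available:
#: the one-way +-20% range read as a 95% confidence interval.
RELATIVE_SE = 0.20 / 1.96


def perturb_parameter(spec: ModelSpec, param_id: str, factor: float) -> ModelSpec:
    """Return a copy of `spec` with one parameter scaled by `factor`.

    Scalar targets are multiplied directly (utilities capped at 1);
    probability-vector components are moved to min(1, c x factor) with the
    rest of the vector renormalised.  The result must re-validate.
    """
    if factor <= 0:
        raise ValueError(f"perturbation factor must be > 0, got {factor}")
    out = spec.model_copy(deep=True)
    for binding in paths.resolve(out, param_id):
        if binding.kind == paths.PROB_VECTOR:
            raise ConfigError(
                f"{param_id}: one-way perturbation targets scalars or single "
                "vector components, not whole vectors"
            )
        value = binding.get()
        if value is None:
            raise ConfigError(f"{param_id}: parameter is unset")
        if binding.kind == paths.PROB_COMPONENT:
            binding.set_renormalized(min(1.0, value * factor))
        elif binding.kind == paths.UTILITY:
            binding.set(min(1.0, value * factor))
        else:
            binding.set(value * factor)
    violations = validate_model(out)
    if violations:
        raise ConfigError(
            f"perturbing {param_id} by {factor} broke the model:\n  "
            + "\n  ".join(violations)
        )
    return out


@dataclass
class TornadoRow:
    """One tornado bar: INMB at the low/high ends of a parameter sweep."""

    param_id: str
    low_inmb: float
    high_inmb: float
    base_inmb: float

    @property
    def width(self) -> float:
        return abs(self.high_inmb - self.low_inmb)


def one_way_tornado(spec: ModelSpec, threshold: float) -> list[TornadoRow]:
    """One-way sweeps of every configured parameter, widest bar first.

    Grouped parameters (several targets under one id) are moved by the same
    factor simultaneously — e.g. a proportion varied in both arms at once.
    """
    if not spec.owsa.parameters:
        raise ConfigError("owsa.parameters is empty: nothing to sweep")
    base = economics.compare_arms(spec)
    base_inmb = economics.inmb(base.delta_cost, base.delta_qalys, threshold)
    p = spec.owsa.perturbation
    rows: list[TornadoRow] = []
    for param in spec.owsa.parameters:
        ends = []
        for factor in (1.0 - p, 1.0 + p):
            varied = spec
            for target in param.targets:
                varied = perturb_parameter(varied, target, factor)
            res = economics.compare_arms(varied)
            ends.append(economics.inmb(res.delta_cost, res.delta_qalys, threshold))
        rows.append(
            TornadoRow(
                param_id=param.id,
                low_inmb=ends[0],
                high_inmb=ends[1],
                base_inmb=base_inmb,
            )
        )
        logger.info("tornado %s: low %.0f, high %.0f", param.id, ends[0], ends[1])
    rows.sort(key=lambda r: r.width, reverse=True)
    return rows


def tornado_dataframe(rows: list[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.param_id,
                "low_inmb": r.low_inmb,
                "high_inmb": r.high_inmb,
                "base_inmb": r.base_inmb,
                "width": r.width,
            }
            for r in rows
        ]
    )


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta(alpha, beta) hyperparameters from mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta mean {mean} must lie strictly in (0, 1)")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ConfigError(
            f"beta moment-matching infeasible: se {se} too large for mean {mean}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma(shape, scale) hyperparameters from mean and SE."""
    if mean <= 0 or se <= 0:
        raise ConfigError(f"gamma moment-matching needs mean, se > 0 (got {mean}, {se})")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def _default_se(mean: float) -> float:
    return RELATIVE_SE * abs(mean)


def _sample_one(
    dist: DistributionSpec, binding: paths.Binding, rng: np.random.Generator
) -> None:
    if dist.kind == "fixed":
        return
    if dist.kind == "dirichlet":
        if binding.kind != paths.PROB_VECTOR:
            raise ConfigError(f"{dist.target}: dirichlet requires a probability vector")
        mean = np.asarray(binding.get(), dtype=float)
        if dist.concentration is not None:
            conc = np.asarray(dist.concentration, dtype=float)
            if len(conc) != len(mean):
                raise ConfigError(f"{dist.target}: concentration length mismatch")
        else:
            conc = mean * dist.ess
        # zero-mass components stay at zero (dirichlet over the support)
        support = conc > 0
        draw = np.zeros_like(mean)
        draw[support] = rng.dirichlet(conc[support])
        binding.set(list(draw))
        return

    value = binding.get()
    mean = dist.mean if dist.mean is not None else float(value)
    se = dist.se if dist.se is not None else _default_se(mean)
    if dist.kind == "beta":
        if binding.kind not in (paths.UTILITY, paths.PROB_COMPONENT, paths.SCALAR):
            raise ConfigError(f"{dist.target}: beta requires a scalar in [0, 1]")
        a, b = beta_from_moments(mean, se)
        draw = float(rng.beta(a, b))
    elif dist.kind == "gamma":
        shape, scale = gamma_from_moments(mean, se)
        draw = float(rng.gamma(shape, scale))
    else:  # pragma: no cover - literal narrows kinds
        raise ConfigError(f"{dist.target}: unknown distribution kind {dist.kind!r}")

    if binding.kind == paths.PROB_COMPONENT:
        binding.set_renormalized(min(1.0, draw))
    else:
        binding.set(draw)


def sample_parameter_set(spec: ModelSpec, rng: np.random.Generator) -> ModelSpec:
    """One coherent parameter draw; parameters marked fixed are untouched."""
    out = spec.model_copy(deep=True)
    for dist in spec.psa.distributions:
        for binding in paths.resolve(out, dist.target):
            _sample_one(dist, binding, rng)
    violations = validate_model(out)
    if violations:
        raise ConfigError(
            "probabilistic draw produced an invalid model:\n  "
            + "\n  ".join(violations)
        )
    return out


@dataclass
class PSAResult:
    """Per-draw increment pairs plus the seed and distributions behind them."""

    seed: int
    n: int
    delta_costs: np.ndarray
    delta_effects: np.ndarray
    distributions: list[DistributionSpec] = field(repr=False)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n),
                "delta_cost": self.delta_costs,
                "delta_qalys": self.delta_effects,
            }
        )

    def probability_cost_effective(self, threshold: float) -> float:
        return float(
            np.mean(self.delta_effects * threshold - self.delta_costs > 0.0)
        )


def run_psa(
    spec: ModelSpec, n: int | None = None, seed: int | None = None
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Every draw is fully re-evaluated through the decision tree, cohort
    engine and economics; an invalid draw raises, it is never skipped.
    """
    n = spec.psa.n if n is None else n
    seed = spec.psa.seed if seed is None else seed
    if n < 1:
        raise ConfigError(f"psa: n must be >= 1, got {n}")
    dc = np.empty(n)
    de = np.empty(n)
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        drawn = sample_parameter_set(spec, rng)
        res = economics.compare_arms(drawn)
        dc[i] = res.delta_cost
        de[i] = res.delta_qalys
    logger.info("psa: %d draws, mean dC %.2f, mean dE %.4f", n, dc.mean(), de.mean())
    return PSAResult(
        seed=seed, n=n, delta_costs=dc, delta_effects=de,
        distributions=list(spec.psa.distributions),
    )


@dataclass
class CEACCurve:
    """Probability the intervention is cost-effective per WTP threshold."""

    thresholds: np.ndarray
    probabilities: np.ndarray

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "probability": self.probabilities}
        )


def ceac(psa: PSAResult, grid) -> CEACCurve:
    """Cost-effectiveness acceptability curve over a threshold grid.

    At each threshold: the fraction of draws with positive incremental net
    monetary benefit (delta_effect x threshold - delta_cost > 0).
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ConfigError("ceac: threshold grid is empty")
    if psa.n == 0:
        raise ConfigError("ceac: no draws")
    nmb = psa.delta_effects[None, :] * grid[:, None] - psa.delta_costs[None, :]
    return CEACCurve(thresholds=grid, probabilities=(nmb > 0.0).mean(axis=1))
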