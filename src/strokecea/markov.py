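"""Markov cohort engine: state propagation and discounted accrual.

The cohort enters at 90 days (0.25 y) with the decision-tree outcome mix,
moves to the 1-year distribution through the 90-day-to-1-year matrix, and
thereafter advances in annual cycles through the annual matrix merged each
cycle with the age-specific background mortality of the general population
(independent competing risks: q_total = 1 - (1 - q_stroke)(1 - q_background),
with surviving destinations rescaled proportionally).

Accrual conventions
-------------------
The first model year is duration-weighted between the two measured time
points: 0.25 y at the 90-day distribution plus 0.75 y at the 1-year
distribution.  Under the default ``start_of_interval`` convention the first
year is undiscounted and the interval ending at year t (t >= 2) is
discounted at exponent t - 1; ``end_of_interval`` shifts every exponent one
year later.  No half-cycle correction is applied — the convention switch is
the sanctioned knob for calibrating against outputs produced under the
other timing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acute_phase
from .config_io import (
    DEAD,
    STATES,
    ArmSpec,
    ConfigError,
    ModelSpec,
    StateDistribution,
    TransitionMatrix,
)

__all__ = [
    "discount_factor",
    "merge_background_mortality",
    "step",
    "Trajectory",
    "AccumulationResult",
    "run_cohort",
    "accumulate_outcomes",
]

logger = logging.getLogger(__name__)


def discount_factor(rate: float, t: float) -> float:
    """Discrete-time discount factor (1 + rate)^(-t)."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return float((1.0 + rate) ** (-t))


def merge_background_mortality(T: TransitionMatrix, q: float) -> TransitionMatrix:
    """Overlay background mortality q on every alive row of T.

    Death probabilities combine as independent competing risks,
    d' = 1 - (1 - d)(1 - q); surviving destinations are rescaled by
    (1 - d')/(1 - d) so each row stays stochastic.  Rows with d = 1 and the
    absorbing dead row are untouched.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"background death probability {q} outside [0, 1]")
    A = T.as_array().copy()
    for i in range(DEAD):
        d = A[i, DEAD]
        if d >= 1.0:
            continue
        d_new = 1.0 - (1.0 - d) * (1.0 - q)
        A[i, :DEAD] *= (1.0 - d_new) / (1.0 - d)
        A[i, DEAD] = d_new
    return TransitionMatrix(rows=A.tolist())


def step(dist: StateDistribution, T: TransitionMatrix) -> StateDistribution:
    """One cycle: row vector times transition matrix."""
    return StateDistribution(probs=list(dist.as_array() @ T.as_array()))


@dataclass
class Trajectory:
    """Cohort state distributions at t = 0.25, 1, 2, ..., horizon (years)."""

    times: list[float]
    dists: list[StateDistribution]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.dists):
            raise ValueError("times and dists must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def dead_fractions(self) -> np.ndarray:
        return np.array([d.probs[DEAD] for d in self.dists])

    def as_dataframe(self) -> pd.DataFrame:
        rows = [
            {"time": t, **d.as_mapping()} for t, d in zip(self.times, self.dists)
        ]
        return pd.DataFrame(rows, columns=["time", *STATES])


@dataclass
class AccumulationResult:
    """Discounted totals plus the per-interval breakdown behind them."""

    total_cost: float
    total_qalys: float
    breakdown: pd.DataFrame = field(repr=False)


def run_cohort(spec: ModelSpec, arm: ArmSpec) -> Trajectory:
    """Propagate one arm's cohort from 90 days to the horizon.

    d(0.25) is the decision-tree 90-day mix; d(1) applies the
    90-day-to-1-year matrix; each later year applies the annual matrix
    merged with background mortality at the cohort's age at interval start
    (start_age + t - 1).  Returns horizon + 1 distributions.
    """
    d = acute_phase.ninety_day_distribution(arm)
    times = [spec.acute_phase_duration]
    dists = [d]

    d = step(d, spec.t_90to1)
    times.append(1.0)
    dists.append(d)

    for t in range(2, spec.horizon + 1):
        age = spec.patient.start_age + t - 1
        q = spec.life_table.annual_death_probability(age)
        T = merge_background_mortality(spec.t_annual, q)
        d = step(d, T)
        times.append(float(t))
        dists.append(d)
    logger.info(
        "cohort run: arm %s, %d intervals, final dead fraction %.4f",
        arm.name, len(times), dists[-1].probs[DEAD],
    )
    return Trajectory(times=times, dists=dists)


def accumulate_outcomes(
    traj: Trajectory, spec: ModelSpec, acute_cost: float
) -> AccumulationResult:
    """Accumulate discounted QALYs and costs over a trajectory.

    QALYs: [0.25 x U(d(0.25)) + 0.75 x U(d(1))] for year 1, then one full
    year at U(d(t)) per later interval, discounted per the convention.
    Costs: the acute cost (undiscounted, at entry) plus the same scheme
    over per-state annual costs.
    """
    if len(traj) != spec.horizon + 1:
        raise ConfigError(
            f"trajectory has {len(traj)} entries, spec horizon {spec.horizon} "
            f"requires {spec.horizon + 1}"
        )
    u = spec.utilities.as_array()
    c = spec.annual_costs.as_array()
    e_rate = spec.discount.effect_rate
    c_rate = spec.discount.cost_rate
    shift = 0 if spec.discount.convention == "start_of_interval" else 1
    dur = spec.acute_phase_duration

    rows = [
        {
            "interval": "acute",
            "time_end": dur,
            "years": 0.0,
            "qaly_undisc": 0.0,
            "qaly_factor": 1.0,
            "cost_undisc": acute_cost,
            "cost_factor": 1.0,
        }
    ]

    arr = [d.as_array() for d in traj.dists]
    # year 1: duration-weighted mix of the two measured time points
    q1 = dur * float(arr[0] @ u) + (1.0 - dur) * float(arr[1] @ u)
    c1 = dur * float(arr[0] @ c) + (1.0 - dur) * float(arr[1] @ c)
    rows.append(
        {
            "interval": "year 1",
            "time_end": 1.0,
            "years": 1.0,
            "qaly_undisc": q1,
            "qaly_factor": discount_factor(e_rate, shift),
            "cost_undisc": c1,
            "cost_factor": discount_factor(c_rate, shift),
        }
    )
    for k in range(2, spec.horizon + 1):
        d_t = arr[k]
        rows.append(
            {
                "interval": f"year {k}",
                "time_end": float(k),
                "years": 1.0,
                "qaly_undisc": float(d_t @ u),
                "qaly_factor": discount_factor(e_rate, k - 1 + shift),
                "cost_undisc": float(d_t @ c),
                "cost_factor": discount_factor(c_rate, k - 1 + shift),
            }
        )

    table = pd.DataFrame(rows)
    table["qaly_disc"] = table["qaly_undisc"] * table["qaly_factor"]
    table["cost_disc"] = table["cost_undisc"] * table["cost_factor"]
    return AccumulationResult(
        total_cost=float(table["cost_disc"].sum()),
        total_qalys=float(table["qaly_disc"].sum()),
        breakdown=table,
    )
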