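"""Comparison statistics: ICER with dominance classification, NMB and INMB.

Increments are intervention minus comparator (the comparator is listed
first in the spec).  On the cost-effectiveness plane the ICER is only
reported as a ratio when both increments share a sign (NE quadrant, or SW
flagged as such); a strategy that is cheaper and at least as effective is
"dominant", the reverse "dominated".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import acute_phase, markov
from .config_io import ArmSpec, ModelSpec

__all__ = ["ICEROutcome", "icer", "inmb", "ArmResult", "CEResult", "compare_arms"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ICEROutcome:
    """Dominance label plus the euro/QALY ratio when one is meaningful."""

    label: str  # dominant | dominated | icer | icer_southwest | equivalent
    value: Optional[float] = None

    def __str__(self) -> str:
        return self.label if self.value is None else f"{self.value:.0f}"


def icer(delta_cost: float, delta_effect: float) -> ICEROutcome:
    """Classify an increment pair on the CE plane.

    dominant: cheaper and no less effective (at least one strict);
    dominated: the reverse; equivalent: both increments zero; otherwise the
    ratio delta_cost / delta_effect (flagged "icer_southwest" when both are
    negative, where lower ratios are worse).
    """
    if delta_cost == 0.0 and delta_effect == 0.0:
        return ICEROutcome("equivalent")
    if delta_cost <= 0.0 and delta_effect >= 0.0:
        return ICEROutcome("dominant")
    if delta_cost >= 0.0 and delta_effect <= 0.0:
        return ICEROutcome("dominated")
    label = "icer" if delta_effect > 0 else "icer_southwest"
    return ICEROutcome(label, delta_cost / delta_effect)


def inmb(delta_cost: float, delta_effect: float, threshold: float) -> float:
    """Incremental net monetary benefit: delta_effect x threshold - delta_cost."""
    if threshold <= 0:
        raise ValueError(f"willingness-to-pay threshold must be > 0, got {threshold}")
    return delta_effect * threshold - delta_cost


@dataclass
class ArmResult:
    name: str
    acute_cost: float
    total_cost: float
    total_qalys: float
    accumulation: markov.AccumulationResult = field(repr=False)


@dataclass
class CEResult:
    """Per-arm totals, increments, ICER-or-dominance and INMB per threshold."""

    comparator: ArmResult
    intervention: ArmResult
    delta_cost: float
    delta_qalys: float
    icer: ICEROutcome
    inmb: dict[float, float]

    def as_dataframe(self) -> pd.DataFrame:
        """Two-row summary mirroring the published results-table layout."""
        thresholds = sorted(self.inmb)
        rows = []
        for arm, inc_c, inc_q, ic, nb in (
            (self.comparator, None, None, None, {t: None for t in thresholds}),
            (self.intervention, self.delta_cost, self.delta_qalys, self.icer, self.inmb),
        ):
            row = {
                "treatment": arm.name,
                "cost": arm.total_cost,
                "increment_cost": inc_c,
                "qaly": arm.total_qalys,
                "increment_qaly": inc_q,
                "icer": str(ic) if ic is not None else None,
            }
            for t in thresholds:
                row[f"inmb_{int(t)}"] = nb[t]
            rows.append(row)
        return pd.DataFrame(rows)


def _run_arm(spec: ModelSpec, arm: ArmSpec) -> ArmResult:
    acute = acute_phase.acute_cost(arm, spec.patient)
    traj = markov.run_cohort(spec, arm)
    acc = markov.accumulate_outcomes(traj, spec, acute)
    return ArmResult(
        name=arm.name,
        acute_cost=acute,
        total_cost=acc.total_cost,
        total_qalys=acc.total_qalys,
        accumulation=acc,
    )


def compare_arms(spec: ModelSpec) -> CEResult:
    """Run both arms under identical conventions and compare them."""
    comp = _run_arm(spec, spec.comparator)
    intv = _run_arm(spec, spec.intervention)
    delta_cost = intv.total_cost - comp.total_cost
    delta_qalys = intv.total_qalys - comp.total_qalys
    outcome = icer(delta_cost, delta_qalys)
    benefits = {
        float(t): inmb(delta_cost, delta_qalys, t) for t in spec.economics.thresholds
    }
    logger.info(
        "comparison %s vs %s: dC=%.2f dE=%.4f -> %s",
        intv.name, comp.name, delta_cost, delta_qalys, outcome,
    )
    return CEResult(
        comparator=comp,
        intervention=intv,
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        icer=outcome,
        inmb=benefits,
    )
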