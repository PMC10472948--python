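"""Decision-tree (acute) phase: treatment costs and the 90-day outcome mix.

The acute phase covers thrombolysis (tenecteplase 0.25 mg/kg or alteplase
0.9 mg/kg), optional endovascular thrombectomy (EVT) for large-vessel-
occlusion populations, and the resulting 90-day mRS distribution per arm.
EVT enters as an expected value over the branch fractions: a fraction of
patients is EVT-eligible, and of those a fraction needs no EVT after
thrombolysis (early recanalisation).  Acute costs accrue at model entry
and are not discounted.
"""

from __future__ import annotations

import itertools
import math

from .config_io import ArmSpec, ConfigError, PatientProfile, StateDistribution

__all__ = ["ivt_drug_cost", "acute_cost", "ninety_day_distribution"]


def ivt_drug_cost(arm: ArmSpec, patient: PatientProfile) -> float:
    """Thrombolytic drug cost (euro) for one patient.

    Flat mode returns the configured list price.  Per-vial mode computes the
    dose as dose_per_kg x weight and searches exhaustively for the cheapest
    combination of catalog vials covering it (vial counts are bounded by
    ceil(dose / smallest vial), so the search is exact).
    """
    if arm.drug_cost_mode == "flat":
        if arm.flat_drug_cost is None:
            raise ConfigError(f"arm {arm.name}: flat_drug_cost not set")
        return float(arm.flat_drug_cost)

    if not arm.vial_catalog:
        raise ConfigError(f"arm {arm.name}: per_vial mode requires a vial catalog")
    dose = arm.dose_per_kg * patient.weight
    smallest = min(v.size_mg for v in arm.vial_catalog)
    max_count = math.ceil(dose / smallest)
    best = math.inf
    for counts in itertools.product(range(max_count + 1), repeat=len(arm.vial_catalog)):
        mg = sum(c * v.size_mg for c, v in zip(counts, arm.vial_catalog))
        if mg + 1e-12 >= dose:
            price = sum(c * v.price for c, v in zip(counts, arm.vial_catalog))
            best = min(best, price)
    if not math.isfinite(best):  # pragma: no cover - max_count guarantees a cover
        raise ConfigError(f"arm {arm.name}: vial catalog cannot cover dose {dose} mg")
    return float(best)


def acute_cost(arm: ArmSpec, patient: PatientProfile) -> float:
    """Expected acute treatment cost per patient (euro, undiscounted).

    drug + administration + P(EVT eligible) x P(EVT actually performed) x EVT cost,
    where P(performed | eligible) = 1 - evt_forgone_fraction (patients who
    recanalise early and need no thrombectomy).
    """
    evt_expected = (
        arm.evt_eligible_fraction * (1.0 - arm.evt_forgone_fraction) * arm.evt_cost
    )
    return ivt_drug_cost(arm, patient) + arm.admin_cost + evt_expected


def ninety_day_distribution(arm: ArmSpec) -> StateDistribution:
    """90-day mRS distribution for the arm, mixing the EVT branches.

    eligible x [(1 - forgone) x dist_with_evt + forgone x dist_no_evt]
    + (1 - eligible) x dist_no_evt.  A mixture of simplex points stays on
    the simplex, so the result is always a valid distribution.
    """
    f_el = arm.evt_eligible_fraction
    f_fo = arm.evt_forgone_fraction
    with_evt = arm.dist90_with_evt_effective.as_array()
    no_evt = arm.dist90_no_evt.as_array()
    mixed = f_el * ((1.0 - f_fo) * with_evt + f_fo * no_evt) + (1.0 - f_el) * no_evt
    dist = StateDistribution(probs=list(mixed))
    bad = dist.violations(f"arm {arm.name} 90-day distribution")
    if bad:
        raise ConfigError("; ".join(bad))
    return dist
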