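"""Incremental routine cost per TCV dose via activity-based allocation.

The routine immunization program's 2022 costs are shared across all
antigens. Two allocation bases apportion them to a single TCV dose:

* dose-proportional — cost types that scale with the number of children
  reached (meetings, per diem, supplies, human resources, printing) are
  divided by total doses delivered;
* volume-proportional — cost types that scale with cold-chain throughput
  (vehicle rental/transport, fuel/maintenance/energy, capital equipment)
  are divided by the total packed volume of vaccines delivered (cm3) and
  multiplied by the packed volume of one TCV dose.

Summing the allocated per-dose cost over cost types gives the incremental
cost to deliver one routine TCV dose, on the assumption that ongoing
routine costs for other antigens do not change when TCV is added.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

from .aggregation import (
    DoseLedger,
    LevelEstimate,
    SurveyDesign,
    weighted_ci,
    weighted_mean,
)
from .costing_core import CostBasis, CostingError, CostMatrix, CostType, Level

__all__ = [
    "AllocationMode",
    "DEFAULT_ALLOCATION_RULES",
    "VaccinePresentation",
    "allocate_dose_proportional",
    "allocate_volume_proportional",
    "routine_tcv_cost_per_dose",
    "routine_tcv_level_estimate",
    "full_allocation",
]


class AllocationMode(str, Enum):
    DOSE_PROPORTIONAL = "dose_proportional"
    VOLUME_PROPORTIONAL = "volume_proportional"


# Printing/stationery is not named in either published group; it scales with
# forms per child, so it defaults to the dose basis (overridable in config).
DEFAULT_ALLOCATION_RULES: dict[CostType, AllocationMode] = {
    CostType.MEETINGS_EVENTS: AllocationMode.DOSE_PROPORTIONAL,
    CostType.PER_DIEM: AllocationMode.DOSE_PROPORTIONAL,
    CostType.SUPPLIES: AllocationMode.DOSE_PROPORTIONAL,
    CostType.HUMAN_RESOURCES: AllocationMode.DOSE_PROPORTIONAL,
    CostType.PRINTING_STATIONERY_COMMS: AllocationMode.DOSE_PROPORTIONAL,
    CostType.VEHICLE_RENTAL_TRANSPORT: AllocationMode.VOLUME_PROPORTIONAL,
    CostType.FUEL_MAINTENANCE_ENERGY: AllocationMode.VOLUME_PROPORTIONAL,
    CostType.CAPITAL_VEHICLES_EQUIPMENT: AllocationMode.VOLUME_PROPORTIONAL,
}


@dataclass(frozen=True)
class VaccinePresentation:
    """Packaging of one antigen: vial size and packed volume per dose."""

    antigen: str
    doses_per_vial: int
    packed_volume_cm3_per_dose: float

    def __post_init__(self) -> None:
        if int(self.doses_per_vial) < 1:
            raise CostingError(f"{self.antigen}: doses per vial must be >= 1")
        if not float(self.packed_volume_cm3_per_dose) > 0:
            raise CostingError(f"{self.antigen}: packed volume must be > 0")


def allocate_dose_proportional(cost_total: float, total_doses: float) -> float:
    """Per-dose share of a cost pool: cost / total doses delivered."""
    if not total_doses > 0:
        raise CostingError("dose-proportional allocation requires > 0 doses")
    return cost_total / total_doses


def allocate_volume_proportional(
    cost_total: float, total_volume_cm3: float, tcv: VaccinePresentation
) -> float:
    """Per-TCV-dose share of a cost pool via packed cold-chain volume.

    cost / total volume gives a cost per cm3, multiplied by the packed
    volume of one TCV dose.
    """
    if not total_volume_cm3 > 0:
        raise CostingError("volume-proportional allocation requires > 0 volume")
    return (cost_total / total_volume_cm3) * tcv.packed_volume_cm3_per_dose


def routine_tcv_cost_per_dose(
    matrix: CostMatrix,
    total_doses: float,
    total_volume_cm3: float,
    tcv: VaccinePresentation,
    basis: CostBasis,
    rules: Mapping[CostType, AllocationMode] = DEFAULT_ALLOCATION_RULES,
) -> float:
    """Allocated cost of one routine TCV dose for a single unit-year.

    Every cost type carrying cost in the matrix must have an allocation
    rule; a missing rule is an error rather than a silent drop.
    """
    totals = matrix.cost_type_totals(basis)
    result = 0.0
    for code, cost in totals.items():
        if cost == 0:
            continue
        cost_type = CostType(code)
        if cost_type not in rules:
            raise CostingError(
                f"no allocation rule for cost type {cost_type.value!r} "
                f"(unit {matrix.unit_id!r})"
            )
        mode = AllocationMode(rules[cost_type])
        if mode is AllocationMode.DOSE_PROPORTIONAL:
            result += allocate_dose_proportional(cost, total_doses)
        else:
            result += allocate_volume_proportional(cost, total_volume_cm3, tcv)
    return result


def routine_tcv_level_estimate(
    matrices: Mapping[str, CostMatrix],
    ledger: DoseLedger,
    design: SurveyDesign,
    level: Level,
    basis: CostBasis,
    tcv: VaccinePresentation,
    rules: Mapping[CostType, AllocationMode] = DEFAULT_ALLOCATION_RULES,
    volumes: Mapping[str, float] | None = None,
    confidence: float = 0.95,
) -> LevelEstimate:
    """Routine TCV per-dose cost at one level, with a design-weighted CI.

    The per-unit allocated value is computed first, then averaged with
    design weights, mirroring the campaign estimator. A single-unit level
    (national) reports the plain allocated value without an interval.
    """
    level = Level(level)
    basis = CostBasis(basis)
    doses = ledger.unit_totals()
    vols = ledger.unit_volumes(volumes)
    values = {}
    costs = {}
    for uid, m in matrices.items():
        if uid not in doses.index:
            raise CostingError(f"unit {uid!r} has no routine dose records")
        values[uid] = routine_tcv_cost_per_dose(
            m, float(doses[uid]), float(vols[uid]), tcv, basis, rules
        )
        costs[uid] = m.total(basis)
    values = pd.Series(values, dtype=float)
    costs = pd.Series(costs, dtype=float)

    if level is Level.NATIONAL or len(values) == 1:
        return LevelEstimate(
            level=level,
            basis=basis,
            n_units=len(values),
            mean_cost=float(costs.mean()),
            mean_doses=float(doses.reindex(values.index).mean()),
            cost_per_dose=float(values.sum() / len(values)),
        )
    ci = weighted_ci(values, design, confidence)
    return LevelEstimate(
        level=level,
        basis=basis,
        n_units=len(values),
        mean_cost=weighted_mean(costs, design),
        mean_doses=float(doses.reindex(values.index).mean()),
        cost_per_dose=weighted_mean(values, design),
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
    )


def full_allocation(
    matrix: CostMatrix,
    ledger: DoseLedger,
    basis: CostBasis,
    presentations: Mapping[str, VaccinePresentation],
    rules: Mapping[CostType, AllocationMode] = DEFAULT_ALLOCATION_RULES,
) -> pd.Series:
    """Allocate a unit's full routine cost across all antigens.

    Returns the total cost attributed to each antigen. Summed over
    antigens this conserves the original cost total exactly: the dose
    pool is split by dose shares and the volume pool by volume shares.
    """
    records = ledger.records[ledger.records["unit_id"] == matrix.unit_id]
    if records.empty:
        raise CostingError(f"no dose records for unit {matrix.unit_id!r}")
    sub = DoseLedger(records)
    doses = sub.records.groupby("intervention")["doses"].sum()
    vol_per_dose = pd.Series(
        {a: p.packed_volume_cm3_per_dose for a, p in presentations.items()}
    ).reindex(doses.index)
    if vol_per_dose.isna().any():
        missing = vol_per_dose.index[vol_per_dose.isna()].tolist()
        raise CostingError(f"no presentation for antigens: {missing}")
    volumes = doses * vol_per_dose

    totals = matrix.cost_type_totals(basis)
    dose_pool = 0.0
    vol_pool = 0.0
    for code, cost in totals.items():
        if cost == 0:
            continue
        cost_type = CostType(code)
        if cost_type not in rules:
            raise CostingError(f"no allocation rule for cost type {cost_type.value!r}")
        if AllocationMode(rules[cost_type]) is AllocationMode.DOSE_PROPORTIONAL:
            dose_pool += cost
        else:
            vol_pool += cost

    out = pd.Series(0.0, index=doses.index)
    if doses.sum() > 0:
        out += dose_pool * doses / doses.sum()
    if volumes.sum() > 0:
        out += vol_pool * volumes / volumes.sum()
    elif vol_pool:
        raise CostingError("volume pool has cost but total packed volume is zero")
    return out
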