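"""Standalone-campaign scenarios: re-pricing an integrated campaign for TCV alone.

Because the campaign delivered four interventions with fully shared
activities, the cost attributable to TCV alone cannot be observed. The
scenario engine rescales each activity's cost by a rule and divides by
TCV doses:

* base — activity costs scale with TCV's share of campaign doses, except
  vaccine distribution & storage, which scales with TCV's share of packed
  cold-chain volume;
* low — 25% of every activity's cost, keeping the base (share) rules for
  service delivery and distribution & storage;
* high — 100% of every activity's cost, keeping the base rules for
  service delivery and waste management.

Whenever the dose share is at least 0.25 (in Malawi it was ~0.46), the
scenario totals are ordered low <= base <= high for any non-negative
cost matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .aggregation import (
    DoseLedger,
    LevelEstimate,
    SurveyDesign,
    combine_levels,
    level_cost_per_dose,
)
from .costing_core import Activity, Context, CostBasis, CostingError, CostMatrix, Level, activities_for

__all__ = [
    "ScalingRule",
    "ScenarioSpec",
    "ShareBasis",
    "base_scenario",
    "low_scenario",
    "high_scenario",
    "compute_shares",
    "apply_scenario",
    "scenario_cost_per_dose",
]


@dataclass(frozen=True)
class ScalingRule:
    """How one activity's cost scales in a standalone-TCV scenario.

    ``kind`` is "fraction" (a fixed multiplier in [0, 1]), "dose_share"
    (TCV doses / all campaign doses) or "volume_share" (TCV packed volume
    / all packed volume).
    """

    kind: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"fraction", "dose_share", "volume_share"}:
            raise CostingError(f"unknown scaling rule kind {self.kind!r}")
        if self.kind == "fraction":
            if self.value is None or not (0.0 <= self.value <= 1.0):
                raise CostingError(f"fraction rule requires a value in [0, 1], got {self.value!r}")

    @classmethod
    def fraction(cls, f: float) -> "ScalingRule":
        return cls("fraction", float(f))

    @classmethod
    def dose_share(cls) -> "ScalingRule":
        return cls("dose_share")

    @classmethod
    def volume_share(cls) -> "ScalingRule":
        return cls("volume_share")

    def factor(self, shares: "ShareBasis") -> float:
        if self.kind == "fraction":
            return float(self.value)
        if self.kind == "dose_share":
            return shares.dose_share
        return shares.volume_share


@dataclass(frozen=True)
class ShareBasis:
    """TCV's share of campaign throughput, on doses and on packed volume."""

    dose_share: float
    volume_share: float

    def __post_init__(self) -> None:
        for name, v in (("dose_share", self.dose_share), ("volume_share", self.volume_share)):
            if not (0.0 < v <= 1.0):
                raise CostingError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named standalone-campaign scenario: one scaling rule per activity."""

    name: str
    rules: Mapping[Activity, ScalingRule]

    def factors(self, shares: ShareBasis) -> dict[Activity, float]:
        return {a: r.factor(shares) for a, r in self.rules.items()}


_CAMPAIGN_ACTIVITIES = tuple(activities_for(Context.CAMPAIGN))


def base_scenario() -> ScenarioSpec:
    """Dose-share scaling everywhere except distribution & storage (volume)."""
    rules = {a: ScalingRule.dose_share() for a in _CAMPAIGN_ACTIVITIES}
    rules[Activity.DISTRIBUTION_STORAGE] = ScalingRule.volume_share()
    return ScenarioSpec("base", rules)


def low_scenario() -> ScenarioSpec:
    """25% of every activity, keeping base rules for service delivery and
    distribution & storage."""
    rules = {a: ScalingRule.fraction(0.25) for a in _CAMPAIGN_ACTIVITIES}
    rules[Activity.SERVICE_DELIVERY] = ScalingRule.dose_share()
    rules[Activity.DISTRIBUTION_STORAGE] = ScalingRule.volume_share()
    return ScenarioSpec("low", rules)


def high_scenario() -> ScenarioSpec:
    """Full cost of every activity, keeping base rules for service delivery
    and waste management."""
    rules = {a: ScalingRule.fraction(1.0) for a in _CAMPAIGN_ACTIVITIES}
    rules[Activity.SERVICE_DELIVERY] = ScalingRule.dose_share()
    rules[Activity.WASTE_MANAGEMENT] = ScalingRule.dose_share()
    return ScenarioSpec("high", rules)


def named_scenarios() -> dict[str, ScenarioSpec]:
    return {s.name: s for s in (base_scenario(), low_scenario(), high_scenario())}


def compute_shares(
    ledger: DoseLedger,
    volumes: Mapping[str, float],
    tcv_code: str = "TCV",
) -> ShareBasis:
    """TCV dose and packed-volume shares from a campaign dose ledger.

    ``volumes`` maps intervention codes to packed cm3 per dose; an
    intervention absent from the map contributes zero volume (vitamin A
    occupies no vaccine cold-chain space).
    """
    totals = ledger.intervention_totals()
    if tcv_code not in totals.index:
        raise CostingError(f"ledger has no {tcv_code!r} doses")
    total_doses = float(totals.sum())
    if not total_doses > 0:
        raise CostingError("ledger has zero total doses")
    vol_per_dose = pd.Series({k: volumes.get(k, 0.0) for k in totals.index})
    vols = totals * vol_per_dose
    total_vol = float(vols.sum())
    if not total_vol > 0:
        raise CostingError("ledger has zero total packed volume")
    return ShareBasis(
        dose_share=float(totals[tcv_code]) / total_doses,
        volume_share=float(vols[tcv_code]) / total_vol,
    )


def apply_scenario(
    matrix: CostMatrix, spec: ScenarioSpec, shares: ShareBasis
) -> CostMatrix:
    """Rescale each activity's cost by the scenario's realized factor.

    Every activity carrying cost (on either basis) must have a rule.
    """
    factors = spec.factors(shares)
    carrying = (matrix.activity_totals(CostBasis.FINANCIAL)
                + matrix.activity_totals(CostBasis.ECONOMIC))
    missing = [
        code
        for code, cost in carrying.items()
        if cost > 0 and Activity(code) not in factors
    ]
    if missing:
        raise CostingError(
            f"scenario {spec.name!r} has no rule for activities with cost: {missing}"
        )
    return matrix.scale_activities(factors)


def scenario_cost_per_dose(
    matrices_by_level: Mapping[Level, Mapping[str, CostMatrix]],
    ledger: DoseLedger,
    design: SurveyDesign,
    spec: ScenarioSpec,
    shares: ShareBasis,
    basis: CostBasis,
    tcv_code: str = "TCV",
    confidence: float = 0.95,
    combine_method: str = "sum_bounds",
) -> tuple[dict[Level, LevelEstimate], LevelEstimate]:
    """Standalone-TCV per-dose cost per level and combined across levels.

    Scenario scaling is applied per sampled unit before weighted
    estimation, so the confidence intervals propagate through the same
    machinery as the main analysis. Denominators are each level's TCV
    doses.
    """
    tcv_ledger = DoseLedger(
        ledger.records[ledger.records["intervention"] == tcv_code]
    )
    per_level: dict[Level, LevelEstimate] = {}
    for level, matrices in matrices_by_level.items():
        level = Level(level)
        adjusted = {uid: apply_scenario(m, spec, shares) for uid, m in matrices.items()}
        per_level[level] = level_cost_per_dose(
            adjusted, tcv_ledger.subset(adjusted.keys()), design, level, basis, confidence
        )
    combined = combine_levels(list(per_level.values()), method=combine_method)
    return per_level, combined
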