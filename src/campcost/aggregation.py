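"""Design-weighted estimation of per-dose delivery costs.

Sampled facilities carry survey design weights (inverse inclusion
probabilities from size-proportional sampling). Per-dose cost at a level
is the weighted mean of per-unit ratios (unit total cost / unit total
doses); at the national level, with a single unit, it is a plain ratio
with no confidence interval. Cross-level combination sums the per-level
point estimates, and by default sums the interval bounds as well, treating
levels without an interval as constants.

The confidence-interval method is a normal approximation using the
design-weighted variance of the weighted (Hajek ratio) mean; a
variance-sum alternative for cross-level combination is available behind
a switch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing_core import CostBasis, CostingError, CostMatrix, Level

__all__ = [
    "SurveyDesign",
    "DoseLedger",
    "LevelEstimate",
    "weighted_mean",
    "weighted_ci",
    "level_cost_per_dose",
    "combine_levels",
    "dose_totals",
    "hr_burden_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurveyDesign:
    """Sampled units with strata and positive design weights.

    ``units`` has columns unit_id, level, stratum, weight; one row per
    sampled unit. Facility weights derive from a size proxy (first-dose
    MRV doses); take-all levels (districts, zones, national) get weight 1.
    """

    units: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.units)
        required = {"unit_id", "level", "stratum", "weight"}
        missing = required - set(df.columns)
        if missing:
            raise CostingError(f"survey design missing columns: {sorted(missing)}")
        if df["unit_id"].duplicated().any():
            dupes = df.loc[df["unit_id"].duplicated(), "unit_id"].tolist()
            raise CostingError(f"duplicate units in survey design: {dupes}")
        if not (df["weight"].astype(float) > 0).all():
            raise CostingError("survey design weights must be > 0")
        object.__setattr__(self, "units", df.reset_index(drop=True))

    @classmethod
    def equal_weights(
        cls, unit_ids: Sequence[str], level: Level, stratum: str = "all"
    ) -> "SurveyDesign":
        return cls(
            pd.DataFrame(
                {
                    "unit_id": list(unit_ids),
                    "level": Level(level).value,
                    "stratum": stratum,
                    "weight": 1.0,
                }
            )
        )

    def weights_for(self, unit_ids: Iterable[str]) -> pd.Series:
        """Design weights aligned to ``unit_ids``; error on a missing unit."""
        table = self.units.set_index("unit_id")["weight"].astype(float)
        ids = list(unit_ids)
        missing = [u for u in ids if u not in table.index]
        if missing:
            raise CostingError(f"units without a design weight: {missing}")
        return table.reindex(ids)


@dataclass(frozen=True)
class DoseLedger:
    """Doses delivered per intervention per unit.

    ``records`` has columns unit_id, intervention, doses and optionally
    packed_volume_cm3_per_dose (needed only for volume-proportional
    allocation in the routine analysis).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = {"unit_id", "intervention", "doses"}
        missing = required - set(df.columns)
        if missing:
            raise CostingError(f"dose ledger missing columns: {sorted(missing)}")
        doses = pd.to_numeric(df["doses"], errors="coerce")
        bad = df.index[doses.isna() | (doses < 0)].tolist()
        if bad:
            raise CostingError(f"dose ledger rows with invalid doses: {bad}")
        df = df.assign(doses=doses)
        object.__setattr__(self, "records", df.reset_index(drop=True))

    def unit_totals(self) -> pd.Series:
        """Total doses per unit, summed over interventions."""
        return self.records.groupby("unit_id")["doses"].sum()

    def unit_volumes(
        self, volumes: Mapping[str, float] | None = None
    ) -> pd.Series:
        """Total packed volume (cm3) per unit: sum of doses x per-dose volume.

        Per-dose volumes come from the ledger column when present, else
        from the ``volumes`` mapping (intervention -> cm3/dose); an
        intervention with no volume anywhere contributes zero (e.g.
        vitamin A, which occupies no vaccine cold-chain volume).
        """
        df = self.records
        if "packed_volume_cm3_per_dose" in df.columns:
            per_dose = pd.to_numeric(
                df["packed_volume_cm3_per_dose"], errors="coerce"
            )
        else:
            per_dose = pd.Series(np.nan, index=df.index)
        if volumes is not None:
            fallback = df["intervention"].map(volumes)
            per_dose = per_dose.fillna(fallback)
        per_dose = per_dose.fillna(0.0)
        return (df["doses"] * per_dose).groupby(df["unit_id"]).sum()

    def intervention_totals(self) -> pd.Series:
        return self.records.groupby("intervention")["doses"].sum()

    def subset(self, unit_ids: Iterable[str]) -> "DoseLedger":
        ids = set(unit_ids)
        return DoseLedger(self.records[self.records["unit_id"].isin(ids)])


@dataclass(frozen=True)
class LevelEstimate:
    """Per-dose cost estimate at one health-system level."""

    level: Level | None
    basis: CostBasis
    n_units: int
    mean_cost: float
    mean_doses: float
    cost_per_dose: float
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def ci(self) -> tuple[float, float] | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return (self.ci_low, self.ci_high)


def _aligned(values: pd.Series | Mapping[str, float]) -> pd.Series:
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        raise CostingError(f"missing values for units: {s.index[s.isna()].tolist()}")
    return s


def weighted_mean(values: pd.Series | Mapping[str, float], design: SurveyDesign) -> float:
    """Design-weighted mean: sum(w_i x_i) / sum(w_i)."""
    s = _aligned(values)
    if s.empty:
        raise CostingError("weighted mean of an empty series")
    w = design.weights_for(s.index).to_numpy()
    x = s.to_numpy()
    return float(np.sum(w * x) / np.sum(w))


def weighted_variance_of_mean(
    values: pd.Series | Mapping[str, float], design: SurveyDesign
) -> float:
    """Variance of the weighted (Hajek ratio) mean.

    With normalized weights w~_i = w_i / sum(w), the estimator is
    n/(n-1) * sum(w~_i^2 (x_i - xbar_w)^2), which reduces to s^2/n under
    equal weights. Strata are ignored in variance estimation.
    """
    s = _aligned(values)
    n = len(s)
    if n < 2:
        raise CostingError("variance requires >= 2 units")
    w = design.weights_for(s.index).to_numpy()
    wn = w / w.sum()
    xbar = float(np.sum(wn * s.to_numpy()))
    return float(n / (n - 1) * np.sum(wn**2 * (s.to_numpy() - xbar) ** 2))


def weighted_ci(
    values: pd.Series | Mapping[str, float],
    design: SurveyDesign,
    confidence: float = 0.95,
) -> tuple[float, float] | None:
    """Normal-approximation CI around the weighted mean; None when n < 2.

    Identical values give a zero-width interval. Mirrors the single-unit
    national level, which is reported without an interval.
    """
    s = _aligned(values)
    if len(s) < 2:
        return None
    mean = weighted_mean(s, design)
    se = math.sqrt(weighted_variance_of_mean(s, design))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return (mean - z * se, mean + z * se)


def unit_totals_from_matrices(
    matrices: Mapping[str, CostMatrix], basis: CostBasis
) -> pd.Series:
    """Total cost per unit from a {unit_id: CostMatrix} mapping."""
    return pd.Series({uid: m.total(basis) for uid, m in matrices.items()}, dtype=float)


def level_cost_per_dose(
    matrices: Mapping[str, CostMatrix] | pd.Series,
    ledger: DoseLedger,
    design: SurveyDesign,
    level: Level,
    basis: CostBasis,
    confidence: float = 0.95,
) -> LevelEstimate:
    """Per-dose cost at one level: weighted mean of per-unit ratios.

    Each unit contributes total cost / total doses over all interventions;
    units with zero doses are excluded with a warning (the ratio is
    undefined) but their costs still count in the level's mean cost. At
    the national level (a single unit) the estimate is the exact ratio of
    totals, with no confidence interval.
    """
    level = Level(level)
    basis = CostBasis(basis)
    if isinstance(matrices, pd.Series):
        costs = matrices.astype(float)
    else:
        costs = unit_totals_from_matrices(matrices, basis)
    doses = ledger.unit_totals().reindex(costs.index)
    if doses.isna().any():
        raise CostingError(
            f"units without dose records: {doses.index[doses.isna()].tolist()}"
        )

    zero = doses.index[doses == 0]
    if len(zero):
        logger.warning(
            "excluding %d unit(s) with zero doses from per-dose estimation: %s",
            len(zero),
            list(zero),
        )
    keep = doses.index[doses > 0]
    ratios = costs.loc[keep] / doses.loc[keep]

    if level is Level.NATIONAL or len(keep) == 1:
        total_cost = float(costs.loc[keep].sum())
        total_doses = float(doses.loc[keep].sum())
        return LevelEstimate(
            level=level,
            basis=basis,
            n_units=len(keep),
            mean_cost=float(costs.mean()),
            mean_doses=float(doses.mean()),
            cost_per_dose=total_cost / total_doses,
        )

    cpd = weighted_mean(ratios, design)
    ci = weighted_ci(ratios, design, confidence)
    return LevelEstimate(
        level=level,
        basis=basis,
        n_units=len(keep),
        mean_cost=weighted_mean(costs, design),
        mean_doses=float(doses.mean()),
        cost_per_dose=cpd,
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
    )


def combine_levels(
    estimates: Sequence[LevelEstimate], method: str = "sum_bounds"
) -> LevelEstimate:
    """Combine per-level per-dose costs into an all-levels estimate.

    The point estimate is the sum of level estimates. With
    ``method="sum_bounds"`` (the default, reproducing the published-table
    arithmetic) the combined interval sums the per-level bounds, treating
    levels without an interval as constants. ``method="variance_sum"``
    instead combines half-widths in quadrature.
    """
    if not estimates:
        raise CostingError("no level estimates to combine")
    bases = {e.basis for e in estimates}
    if len(bases) > 1:
        raise CostingError(f"mixed cost bases in combination: {sorted(b.value for b in bases)}")
    point = sum(e.cost_per_dose for e in estimates)
    has_ci = any(e.ci is not None for e in estimates)
    low = high = None
    if has_ci:
        if method == "sum_bounds":
            low = sum(e.ci_low if e.ci_low is not None else e.cost_per_dose for e in estimates)
            high = sum(e.ci_high if e.ci_high is not None else e.cost_per_dose for e in estimates)
        elif method == "variance_sum":
            hw2 = sum(
                ((e.ci_high - e.ci_low) / 2.0) ** 2
                for e in estimates
                if e.ci is not None
            )
            hw = math.sqrt(hw2)
            low, high = point - hw, point + hw
        else:
            raise CostingError(f"unknown CI combination method {method!r}")
    return LevelEstimate(
        level=None,
        basis=bases.pop(),
        n_units=sum(e.n_units for e in estimates),
        mean_cost=float("nan"),
        mean_doses=float("nan"),
        cost_per_dose=float(point),
        ci_low=low,
        ci_high=high,
    )


def dose_totals(ledger: DoseLedger) -> pd.DataFrame:
    """Per-intervention dose sums and means across units, plus a total row."""
    if ledger.records.empty:
        raise CostingError("dose ledger is empty")
    by = ledger.records.groupby("intervention")["doses"]
    table = pd.DataFrame({"total_doses": by.sum(), "mean_doses": by.mean()})
    overall = pd.DataFrame(
        {
            "total_doses": [table["total_doses"].sum()],
            "mean_doses": [ledger.unit_totals().mean()],
        },
        index=pd.Index(["all_interventions"], name="intervention"),
    )
    return pd.concat([table, overall])


def hr_burden_summary(records: pd.DataFrame) -> pd.Series:
    """Workforce burden summary across units.

    ``records`` has columns unit_id, persons, hired, overtime_hours
    (0 when no longer working days were reported). Returns mean/min/max
    persons involved, mean persons hired, the share of units reporting
    longer days, and the mean extra hours among those units.
    """
    df = pd.DataFrame(records)
    for col in ("persons", "hired", "overtime_hours"):
        if col not in df.columns:
            raise CostingError(f"hr records missing column {col!r}")
        if (pd.to_numeric(df[col], errors="coerce") < 0).any():
            raise CostingError(f"negative values in hr column {col!r}")
    longer = df["overtime_hours"] > 0
    return pd.Series(
        {
            "persons_mean": df["persons"].mean(),
            "persons_min": df["persons"].min(),
            "persons_max": df["persons"].max(),
            "hired_mean": df["hired"].mean(),
            "share_longer_days": float(longer.mean()),
            "overtime_mean_hours": float(df.loc[longer, "overtime_hours"].mean())
            if longer.any()
            else 0.0,
        }
    )
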