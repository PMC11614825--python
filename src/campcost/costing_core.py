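"""Cost taxonomy and monetary primitives for immunization micro-costing.

This module defines the atoms of the analysis: health-system levels,
program activities and cost types, financial vs. economic cost bases,
line-item cost records, capital assets with annuity-factor annualization,
currency conversion, and the per-unit activity x cost-type cost matrix.

All monetary data are collected in Malawian Kwacha (MWK) and converted to
2020 US$ before any aggregation, so every matrix and report downstream is
in a single currency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CostingError",
    "CurrencyError",
    "Level",
    "Context",
    "Activity",
    "CostType",
    "CostBasis",
    "Currency",
    "MonetaryAmount",
    "CostLineItem",
    "CapitalAsset",
    "CostMatrix",
    "activities_for",
    "line_cost",
    "annuity_factor",
    "annualize_capital",
    "convert_currency",
    "unit_cost_matrix",
]


class CostingError(ValueError):
    """Raised when an input violates a costing-domain invariant."""


class CurrencyError(CostingError):
    """Raised on arithmetic or conversion between mismatched currencies."""


class Level(str, Enum):
    """Tier of the health system at which a cost or dose is recorded.

    Zones participate only in routine vaccine storage and distribution;
    they had no role in the integrated campaign.
    """

    FACILITY = "facility"
    DISTRICT = "district"
    ZONE = "zone"
    NATIONAL = "national"


class Context(str, Enum):
    """Program context: a mass campaign or the routine immunization year."""

    CAMPAIGN = "campaign"
    ROUTINE = "routine"


class Activity(str, Enum):
    """Program activity categories.

    ``ESTIMATING_DEMAND`` applies only to routine costing;
    ``AEFI_MANAGEMENT`` (adverse events following immunization)
    only to campaign costing.
    """

    ESTIMATING_DEMAND = "estimating_demand"
    TRAINING = "training"
    MANAGEMENT = "management"
    SOCIAL_MOBILIZATION = "social_mobilization"
    DISTRIBUTION_STORAGE = "distribution_storage"
    SERVICE_DELIVERY = "service_delivery"
    SUPERVISION = "supervision"
    WASTE_MANAGEMENT = "waste_management"
    AEFI_MANAGEMENT = "aefi_management"
    RECORD_KEEPING = "record_keeping"


_ROUTINE_ONLY = frozenset({Activity.ESTIMATING_DEMAND})
_CAMPAIGN_ONLY = frozenset({Activity.AEFI_MANAGEMENT})


def activities_for(context: Context) -> tuple[Activity, ...]:
    """Activities applicable in the given program context."""
    context = Context(context)
    excluded = _ROUTINE_ONLY if context is Context.CAMPAIGN else _CAMPAIGN_ONLY
    return tuple(a for a in Activity if a not in excluded)


class CostType(str, Enum):
    """Resource/input categories.

    Supplies exclude commodities (vaccines, vitamin A, syringes, safety
    boxes); commodity costs are out of scope for this analysis.
    """

    MEETINGS_EVENTS = "meetings_events"
    HUMAN_RESOURCES = "human_resources"
    FUEL_MAINTENANCE_ENERGY = "fuel_maintenance_energy"
    CAPITAL_VEHICLES_EQUIPMENT = "capital_vehicles_equipment"
    VEHICLE_RENTAL_TRANSPORT = "vehicle_rental_transport"
    PRINTING_STATIONERY_COMMS = "printing_stationery_comms"
    PER_DIEM = "per_diem"
    SUPPLIES = "supplies"


class CostBasis(str, Enum):
    """Financial = direct expenditure; economic = financial + opportunity."""

    FINANCIAL = "financial"
    ECONOMIC = "economic"


class Currency(str, Enum):
    MWK = "MWK"
    USD2020 = "USD2020"


#: World Bank official exchange rate for 2020, MWK per US$.
DEFAULT_EXCHANGE_RATE = 749.53
#: Standard discount rate for capital annualization.
DEFAULT_DISCOUNT_RATE = 0.03


@dataclass(frozen=True)
class MonetaryAmount:
    """A non-negative amount in a single currency.

    Arithmetic is only defined between amounts of identical currency;
    mixing raises :class:`CurrencyError` rather than silently coercing.
    """

    value: float
    currency: Currency = Currency.MWK

    def __post_init__(self) -> None:
        object.__setattr__(self, "currency", Currency(self.currency))
        v = float(self.value)
        if not math.isfinite(v) or v < 0:
            raise CostingError(f"monetary amount must be finite and >= 0, got {self.value!r}")
        object.__setattr__(self, "value", v)

    def __add__(self, other: "MonetaryAmount") -> "MonetaryAmount":
        if not isinstance(other, MonetaryAmount):
            return NotImplemented
        if other.currency is not self.currency:
            raise CurrencyError(
                f"cannot add {self.currency.value} and {other.currency.value}"
            )
        return MonetaryAmount(self.value + other.value, self.currency)

    def __mul__(self, factor: float) -> "MonetaryAmount":
        return MonetaryAmount(self.value * float(factor), self.currency)

    __rmul__ = __mul__


@dataclass(frozen=True)
class CostLineItem:
    """One resource use: where, in what activity, of what cost type.

    ``opportunity_flag`` distinguishes direct expenditure (False) from
    opportunity cost (True, e.g. existing staff time diverted to the
    campaign). The flag lives on the line item rather than the cost type
    because human-resource time can be either: staff hired for the campaign
    are a financial cost, seconded staff an opportunity cost.
    """

    unit_id: str
    level: Level
    context: Context
    activity: Activity
    cost_type: CostType
    quantity: float
    unit_cost: MonetaryAmount
    opportunity_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", Level(self.level))
        object.__setattr__(self, "context", Context(self.context))
        object.__setattr__(self, "activity", Activity(self.activity))
        object.__setattr__(self, "cost_type", CostType(self.cost_type))
        q = float(self.quantity)
        if not math.isfinite(q) or q < 0:
            raise CostingError(
                f"line item for unit {self.unit_id!r}: quantity must be finite "
                f"and >= 0, got {self.quantity!r}"
            )
        object.__setattr__(self, "quantity", q)
        if self.activity not in activities_for(self.context):
            raise CostingError(
                f"line item for unit {self.unit_id!r}: activity "
                f"{self.activity.value!r} is not applicable in the "
                f"{self.context.value} context"
            )


@dataclass(frozen=True)
class CapitalAsset:
    """A capital purchase depreciated over its useful life.

    ``campaign_purchase`` marks an asset bought specifically during the
    campaign period, in which case its annualized cost also counts as a
    financial cost; otherwise capital is an economic-only cost.
    """

    unit_id: str
    description: str
    price: MonetaryAmount
    useful_life_years: int
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    campaign_purchase: bool = False

    def __post_init__(self) -> None:
        if int(self.useful_life_years) < 1:
            raise CostingError(
                f"asset {self.description!r} (unit {self.unit_id!r}): "
                f"useful life must be >= 1 year, got {self.useful_life_years!r}"
            )
        object.__setattr__(self, "useful_life_years", int(self.useful_life_years))
        r = float(self.discount_rate)
        if not (0.0 <= r < 1.0):
            raise CostingError(
                f"asset {self.description!r}: discount rate must be in [0, 1), got {r}"
            )
        object.__setattr__(self, "discount_rate", r)


def line_cost(item: CostLineItem) -> MonetaryAmount:
    """Cost of one line item: quantity x unit cost, in the item's currency."""
    return item.unit_cost * item.quantity


def annuity_factor(rate: float, years: int) -> float:
    """Present value of a 1-per-year annuity over ``years`` at ``rate``.

    A(r, L) = (1 - (1 + r)^-L) / r, with the analytic zero-rate limit
    A(0, L) = L (straight-line depreciation).
    """
    if years < 1:
        raise CostingError(f"annuity factor requires >= 1 year, got {years}")
    if rate == 0.0:
        return float(years)
    return (1.0 - (1.0 + rate) ** -years) / rate


def annualize_capital(asset: CapitalAsset) -> MonetaryAmount:
    """Annual equivalent cost of a capital asset.

    The purchase price is spread over the useful life with an annuity
    factor at the configured discount rate, the convention in
    immunization-costing guidance. At r = 0 this is price / L.
    """
    factor = annuity_factor(asset.discount_rate, asset.useful_life_years)
    return MonetaryAmount(asset.price.value / factor, asset.price.currency)


def convert_currency(
    amount: MonetaryAmount, rate: float = DEFAULT_EXCHANGE_RATE
) -> MonetaryAmount:
    """Convert an MWK amount to 2020 US$ at ``rate`` MWK per dollar."""
    if amount.currency is not Currency.MWK:
        raise CurrencyError(
            f"can only convert MWK amounts, got {amount.currency.value}"
        )
    if not rate > 0:
        raise CostingError(f"exchange rate must be > 0, got {rate}")
    return MonetaryAmount(amount.value / rate, Currency.USD2020)


def _to_usd(amount: MonetaryAmount, rate: float) -> float:
    if amount.currency is Currency.USD2020:
        return amount.value
    return convert_currency(amount, rate).value


@dataclass
class CostMatrix:
    """Activity x cost-type totals for one unit (or one level), in 2020 US$.

    Holds one grid per cost basis. The economic grid includes every
    financial cell plus opportunity costs and annualized capital, so
    economic >= financial cell-wise for valid inputs.
    """

    unit_id: str | None
    level: Level | None
    context: Context
    financial: pd.DataFrame
    economic: pd.DataFrame

    @staticmethod
    def _empty_grid() -> pd.DataFrame:
        return pd.DataFrame(
            0.0,
            index=pd.Index([a.value for a in Activity], name="activity"),
            columns=pd.Index([c.value for c in CostType], name="cost_type"),
        )

    @classmethod
    def zeros(
        cls, unit_id: str | None, level: Level | None, context: Context
    ) -> "CostMatrix":
        return cls(
            unit_id=unit_id,
            level=Level(level) if level is not None else None,
            context=Context(context),
            financial=cls._empty_grid(),
            economic=cls._empty_grid(),
        )

    def grid(self, basis: CostBasis) -> pd.DataFrame:
        return self.financial if CostBasis(basis) is CostBasis.FINANCIAL else self.economic

    def total(self, basis: CostBasis) -> float:
        return float(self.grid(basis).to_numpy().sum())

    def activity_totals(self, basis: CostBasis) -> pd.Series:
        return self.grid(basis).sum(axis=1)

    def cost_type_totals(self, basis: CostBasis) -> pd.Series:
        return self.grid(basis).sum(axis=0)

    def activity_shares(self, basis: CostBasis) -> pd.Series:
        totals = self.activity_totals(basis)
        denom = totals.sum()
        return totals / denom if denom > 0 else totals * 0.0

    def cost_type_shares(self, basis: CostBasis) -> pd.Series:
        totals = self.cost_type_totals(basis)
        denom = totals.sum()
        return totals / denom if denom > 0 else totals * 0.0

    def __add__(self, other: "CostMatrix") -> "CostMatrix":
        if not isinstance(other, CostMatrix):
            return NotImplemented
        if other.context is not self.context:
            raise CostingError("cannot add matrices from different contexts")
        return CostMatrix(
            unit_id=self.unit_id if self.unit_id == other.unit_id else None,
            level=self.level if self.level == other.level else None,
            context=self.context,
            financial=self.financial + other.financial,
            economic=self.economic + other.economic,
        )

    def scale_activities(self, factors: Mapping[Activity, float]) -> "CostMatrix":
        """Return a copy with each activity row multiplied by its factor.

        Activities absent from ``factors`` keep factor 1. Used by the
        standalone-campaign scenario engine.
        """
        fin = self.financial.copy()
        eco = self.economic.copy()
        for activity, f in factors.items():
            key = Activity(activity).value
            fin.loc[key] *= f
            eco.loc[key] *= f
        return replace(self, financial=fin, economic=eco)


def unit_cost_matrix(
    items: Iterable[CostLineItem],
    assets: Sequence[CapitalAsset] = (),
    *,
    unit_id: str | None = None,
    level: Level | None = None,
    context: Context | None = None,
    exchange_rate: float = DEFAULT_EXCHANGE_RATE,
    capital_period_fraction: float = 1.0,
    capital_activity: Activity = Activity.DISTRIBUTION_STORAGE,
) -> CostMatrix:
    """Sum line items (and annualized capital) into one unit's cost matrix.

    Financial cells sum direct-expenditure lines; economic cells sum all
    lines. Annualized capital enters the economic grid under
    ``capital_vehicles_equipment`` scaled by ``capital_period_fraction``
    (1 for a routine year, a configured fraction such as 1/12 for a
    one-month campaign); it also enters the financial grid when the asset
    is flagged as a campaign-period purchase. All values are converted to
    2020 US$ before summation.

    Raises :class:`CostingError` on mixed unit ids or contexts.
    """
    items = list(items)
    if items:
        unit_ids = {it.unit_id for it in items}
        contexts = {it.context for it in items}
        if len(unit_ids) > 1:
            raise CostingError(f"items span multiple units: {sorted(unit_ids)}")
        if len(contexts) > 1:
            raise CostingError("items span multiple contexts")
        unit_id = unit_id or items[0].unit_id
        level = level if level is not None else items[0].level
        context = context or items[0].context
    if context is None:
        raise CostingError("context required when the item list is empty")
    matrix = CostMatrix.zeros(unit_id, level, Context(context))

    for it in items:
        cost_usd = _to_usd(line_cost(it), exchange_rate)
        matrix.economic.loc[it.activity.value, it.cost_type.value] += cost_usd
        if not it.opportunity_flag:
            matrix.financial.loc[it.activity.value, it.cost_type.value] += cost_usd

    col = CostType.CAPITAL_VEHICLES_EQUIPMENT.value
    row = Activity(capital_activity).value
    for asset in assets:
        if unit_id is not None and asset.unit_id != unit_id:
            raise CostingError(
                f"asset {asset.description!r} belongs to unit {asset.unit_id!r}, "
                f"not {unit_id!r}"
            )
        annual_usd = _to_usd(annualize_capital(asset), exchange_rate)
        period_cost = annual_usd * capital_period_fraction
        matrix.economic.loc[row, col] += period_cost
        if asset.campaign_purchase:
            matrix.financial.loc[row, col] += period_cost
    return matrix
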