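"""Run configuration: exchange rate, discounting, CI options, presentations."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .costing_core import (
    DEFAULT_DISCOUNT_RATE,
    DEFAULT_EXCHANGE_RATE,
    CostingError,
    CostType,
)
from .routine_allocation import (
    DEFAULT_ALLOCATION_RULES,
    AllocationMode,
    VaccinePresentation,
)

__all__ = ["AnalysisConfig", "DEFAULT_PRESENTATIONS"]


# Packed cold-chain volumes (cm3 per dose) for a typical EPI schedule.
# The TCV figure is a placeholder assumption (5-dose-vial class); the source
# study does not publish it, so analyses must set it explicitly in config.
DEFAULT_PRESENTATIONS: tuple[VaccinePresentation, ...] = (
    VaccinePresentation("BCG", 20, 1.2),
    VaccinePresentation("bOPV", 20, 1.0),
    VaccinePresentation("PENTA", 10, 2.6),
    VaccinePresentation("PCV", 4, 4.8),
    VaccinePresentation("ROTA", 1, 17.1),
    VaccinePresentation("MRV", 10, 3.5),
    VaccinePresentation("TCV", 5, 3.0),
    VaccinePresentation("vitA", 1, 0.0001),  # negligible cold-chain volume
)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the costing analysis.

    ``campaign_capital_fraction`` apportions annualized capital to a
    one-month campaign (default 1/12 of the annual cost); a routine year
    carries the full annual cost.
    """

    exchange_rate_mwk_per_usd: float = DEFAULT_EXCHANGE_RATE
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    campaign_capital_fraction: float = 1.0 / 12.0
    ci_confidence: float = 0.95
    combine_ci_method: str = "sum_bounds"  # or "variance_sum"
    allocation_rules: dict[CostType, AllocationMode] = field(
        default_factory=lambda: dict(DEFAULT_ALLOCATION_RULES)
    )
    presentations: dict[str, VaccinePresentation] = field(
        default_factory=lambda: {p.antigen: p for p in DEFAULT_PRESENTATIONS}
    )
    tcv_code: str = "TCV"

    def __post_init__(self) -> None:
        if not self.exchange_rate_mwk_per_usd > 0:
            raise CostingError("exchange rate must be > 0")
        if not (0.0 <= self.discount_rate < 1.0):
            raise CostingError("discount rate must be in [0, 1)")
        if not (0.0 < self.campaign_capital_fraction <= 1.0):
            raise CostingError("campaign capital fraction must be in (0, 1]")

    @property
    def tcv(self) -> VaccinePresentation:
        if self.tcv_code not in self.presentations:
            raise CostingError(
                f"no presentation configured for TCV code {self.tcv_code!r}"
            )
        return self.presentations[self.tcv_code]

    @property
    def volumes(self) -> dict[str, float]:
        return {a: p.packed_volume_cm3_per_dose for a, p in self.presentations.items()}

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        kwargs: dict = {}
        for key in (
            "exchange_rate_mwk_per_usd",
            "discount_rate",
            "campaign_capital_fraction",
            "ci_confidence",
            "combine_ci_method",
            "tcv_code",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "allocation_rules" in raw:
            kwargs["allocation_rules"] = {
                CostType(k): AllocationMode(v) for k, v in raw["allocation_rules"].items()
            }
        if "presentations" in raw:
            kwargs["presentations"] = {
                p["antigen"]: VaccinePresentation(
                    p["antigen"],
                    int(p.get("doses_per_vial", 1)),
                    float(p["packed_volume_cm3_per_dose"]),
                )
                for p in raw["presentations"]
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)
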