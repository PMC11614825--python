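"""Shared fixtures: published-table-calibrated inputs and small synthetic bundles."""

from __future__ import annotations

import pandas as pd
import pytest

from campcost import (
    Activity,
    Context,
    CostLineItem,
    CostType,
    Currency,
    DoseLedger,
    Level,
    MonetaryAmount,
    StudyInputs,
    SurveyDesign,
)
from campcost.costing_core import DEFAULT_EXCHANGE_RATE

# Published integrated-campaign magnitudes (2020 US$ / doses) used to
# calibrate fixtures: per-level dose means/totals and per-dose cells.
FACILITY_DOSE_MEANS = {"TCV": 13347, "MRV": 5428, "bOPV": 5749, "vitA": 5153}
DISTRICT_DOSE_MEANS = {"TCV": 326439, "MRV": 123885, "bOPV": 134219, "vitA": 127513}
NATIONAL_DOSE_TOTALS = {"TCV": 7043335, "MRV": 2646095, "bOPV": 2925288, "vitA": 2620670}
NATIONAL_FIN_COST = 2_155_830.0
NATIONAL_ECO_COST = 2_180_366.0


def _cost_lines(uid: str, level: Level, fin_usd: float, eco_usd: float) -> list[CostLineItem]:
    """Two-line unit: one financial, one opportunity, in MWK."""
    rate = DEFAULT_EXCHANGE_RATE
    lines = [
        CostLineItem(
            unit_id=uid, level=level, context=Context.CAMPAIGN,
            activity=Activity.SERVICE_DELIVERY, cost_type=CostType.SUPPLIES,
            quantity=1.0, unit_cost=MonetaryAmount(fin_usd * rate, Currency.MWK),
            opportunity_flag=False,
        )
    ]
    opp = eco_usd - fin_usd
    if opp > 0:
        lines.append(
            CostLineItem(
                unit_id=uid, level=level, context=Context.CAMPAIGN,
                activity=Activity.SERVICE_DELIVERY,
                cost_type=CostType.HUMAN_RESOURCES,
                quantity=1.0, unit_cost=MonetaryAmount(opp * rate, Currency.MWK),
                opportunity_flag=True,
            )
        )
    return lines


@pytest.fixture
def table_calibrated_campaign() -> StudyInputs:
    """Campaign inputs whose per-level per-dose ratios equal the published
    cells: facility $0.01/$0.35, district $0.34/$0.35, national the exact
    cost/dose ratio of the printed totals."""
    fac_doses = sum(FACILITY_DOSE_MEANS.values())      # 29,677
    dist_doses = sum(DISTRICT_DOSE_MEANS.values())     # 712,056
    items: list[CostLineItem] = []
    dose_rows = []
    design_rows = []

    for uid in ("F001", "F002"):
        items += _cost_lines(uid, Level.FACILITY, 0.01 * fac_doses, 0.35 * fac_doses)
        for name, d in FACILITY_DOSE_MEANS.items():
            dose_rows.append({"unit_id": uid, "intervention": name, "doses": d})
        design_rows.append({"unit_id": uid, "level": "facility", "stratum": "all", "weight": 1.0})
    for uid in ("D01", "D02"):
        items += _cost_lines(uid, Level.DISTRICT, 0.34 * dist_doses, 0.35 * dist_doses)
        for name, d in DISTRICT_DOSE_MEANS.items():
            dose_rows.append({"unit_id": uid, "intervention": name, "doses": d})
        design_rows.append({"unit_id": uid, "level": "district", "stratum": "all", "weight": 1.0})

    items += _cost_lines("NAT", Level.NATIONAL, NATIONAL_FIN_COST, NATIONAL_ECO_COST)
    for name, d in NATIONAL_DOSE_TOTALS.items():
        dose_rows.append({"unit_id": "NAT", "intervention": name, "doses": d})
    design_rows.append({"unit_id": "NAT", "level": "national", "stratum": "all", "weight": 1.0})

    return StudyInputs(
        context=Context.CAMPAIGN,
        line_items=items,
        assets=[],
        ledger=DoseLedger(pd.DataFrame(dose_rows)),
        design=SurveyDesign(pd.DataFrame(design_rows)),
    )


@pytest.fixture(scope="session")
def small_campaign_study():
    from campcost import generate_campaign

    return generate_campaign(seed=7)


@pytest.fixture(scope="session")
def small_routine_study():
    from campcost import generate_routine

    return generate_routine(seed=7)
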