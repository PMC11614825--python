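"""Monetary arithmetic, capital annualization, and unit cost matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from campcost import (
    Activity,
    CapitalAsset,
    Context,
    CostBasis,
    CostingError,
    CostLineItem,
    CostType,
    CurrencyError,
    Level,
    MonetaryAmount,
    annualize_capital,
    convert_currency,
    line_cost,
    unit_cost_matrix,
)
from campcost.costing_core import Currency, annuity_factor


def _item(quantity, unit_cost_mwk, opportunity=False, unit_id="F001",
          activity=Activity.SERVICE_DELIVERY, cost_type=CostType.SUPPLIES):
    return CostLineItem(
        unit_id=unit_id, level=Level.FACILITY, context=Context.CAMPAIGN,
        activity=activity, cost_type=cost_type, quantity=quantity,
        unit_cost=MonetaryAmount(unit_cost_mwk, Currency.MWK),
        opportunity_flag=opportunity,
    )


class TestLineCost:
    @pytest.mark.parametrize(
        "quantity, unit_cost, expected",
        [
            (0.0, 12345.0, 0.0),
            (10.0, 7495.30, 74953.00),
            (1.0, 749.53, 749.53),
        ],
    )
    def test_quantity_times_unit_cost(self, quantity, unit_cost, expected):
        cost = line_cost(_item(quantity, unit_cost))
        assert cost.value == pytest.approx(expected)
        assert cost.currency is Currency.MWK

    def test_one_dollar_line(self):
        # 749.53 MWK is exactly one 2020 US$ at the official rate
        usd = convert_currency(line_cost(_item(1.0, 749.53)))
        assert usd.value == pytest.approx(1.0)

    def test_negative_quantity_names_unit(self):
        with pytest.raises(CostingError, match="F001"):
            _item(-1.0, 100.0)


class TestAnnualization:
    def test_zero_rate_is_straight_line(self):
        asset = CapitalAsset("NAT", "truck", MonetaryAmount(1000.0), 5, 0.0)
        assert annualize_capital(asset).value == pytest.approx(200.0)

    def test_matches_discounted_stream_example(self):
        asset = CapitalAsset("NAT", "cold room", MonetaryAmount(100_000.0), 10, 0.03)
        assert annualize_capital(asset).value == pytest.approx(11_723.05, abs=0.01)

    def test_one_year_life(self):
        asset = CapitalAsset("NAT", "tent", MonetaryAmount(500.0), 1, 0.03)
        assert annualize_capital(asset).value == pytest.approx(500.0 * 1.03)

    @pytest.mark.parametrize("rate", [0.0, 0.01, 0.03, 0.1])
    @pytest.mark.parametrize("years", list(range(1, 31)))
    def test_annuity_equals_discounted_stream_oracle(self, rate, years):
        # independent oracle: sum the discounted unit stream term by term
        stream = sum((1.0 + rate) ** -t for t in range(1, years + 1))
        assert annuity_factor(rate, years) == pytest.approx(stream, rel=1e-9)

    def test_annualized_never_exceeds_price(self):
        for years in (1, 2, 10, 30):
            asset = CapitalAsset("D01", "car", MonetaryAmount(9999.0), years, 0.03)
            # the L=1 annuity factor is 1/(1+r) < 1, so allow that one year
            assert annualize_capital(asset).value <= 9999.0 * 1.03 + 1e-9

    def test_zero_life_rejected(self):
        with pytest.raises(CostingError):
            CapitalAsset("D01", "car", MonetaryAmount(1.0), 0, 0.03)


class TestCurrency:
    @pytest.mark.parametrize(
        "mwk, usd", [(749.53, 1.0), (0.0, 0.0), (374_765.00, 500.0)]
    )
    def test_conversion(self, mwk, usd):
        out = convert_currency(MonetaryAmount(mwk, Currency.MWK), 749.53)
        assert out.value == pytest.approx(usd)
        assert out.currency is Currency.USD2020

    def test_converting_usd_raises(self):
        with pytest.raises(CurrencyError):
            convert_currency(MonetaryAmount(1.0, Currency.USD2020), 749.53)

    def test_mixed_currency_addition_raises(self):
        with pytest.raises(CurrencyError):
            MonetaryAmount(1.0, Currency.MWK) + MonetaryAmount(1.0, Currency.USD2020)

    @given(st.lists(st.floats(min_value=0.0, max_value=1e9), min_size=1, max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_conversion_is_linear(self, values):
        # convert-then-sum equals sum-then-convert
        rate = 749.53
        summed_first = convert_currency(MonetaryAmount(sum(values)), rate).value
        converted_first = sum(
            convert_currency(MonetaryAmount(v), rate).value for v in values
        )
        assert converted_first == pytest.approx(summed_first, rel=1e-9, abs=1e-12)


class TestUnitCostMatrix:
    def test_empty_items_give_zero_matrix(self):
        m = unit_cost_matrix([], context=Context.CAMPAIGN)
        assert m.total(CostBasis.FINANCIAL) == 0.0
        assert m.total(CostBasis.ECONOMIC) == 0.0

    def test_same_cell_sums(self):
        rate = 749.53
        items = [_item(1.0, 100.0 * rate), _item(1.0, 50.0 * rate)]
        m = unit_cost_matrix(items)
        cell = m.financial.loc[
            Activity.SERVICE_DELIVERY.value, CostType.SUPPLIES.value
        ]
        assert cell == pytest.approx(150.0)
        assert m.total(CostBasis.FINANCIAL) == pytest.approx(150.0)
        assert m.total(CostBasis.ECONOMIC) == pytest.approx(150.0)

    def test_opportunity_cost_widens_economic_only(self):
        # a unit with $100 spending and $900 of seconded staff time:
        # financial total 100, economic total 1,000
        rate = 749.53
        items = [
            _item(1.0, 100.0 * rate),
            _item(1.0, 900.0 * rate, opportunity=True,
                  cost_type=CostType.HUMAN_RESOURCES),
        ]
        m = unit_cost_matrix(items)
        assert m.total(CostBasis.FINANCIAL) == pytest.approx(100.0)
        assert m.total(CostBasis.ECONOMIC) == pytest.approx(1000.0)

    def test_capital_is_economic_only_by_default(self):
        asset = CapitalAsset("F001", "fridge", MonetaryAmount(749.53 * 1000), 10, 0.0)
        m = unit_cost_matrix([_item(1.0, 749.53)], [asset])
        assert m.total(CostBasis.FINANCIAL) == pytest.approx(1.0)
        assert m.total(CostBasis.ECONOMIC) == pytest.approx(101.0)

    def test_campaign_purchase_capital_is_financial_too(self):
        asset = CapitalAsset(
            "F001", "tent", MonetaryAmount(749.53 * 100), 1, 0.0,
            campaign_purchase=True,
        )
        m = unit_cost_matrix([], [asset], unit_id="F001", context=Context.CAMPAIGN)
        assert m.total(CostBasis.FINANCIAL) == pytest.approx(100.0)

    def test_mixed_unit_ids_rejected(self):
        with pytest.raises(CostingError, match="multiple units"):
            unit_cost_matrix([_item(1, 1, unit_id="A"), _item(1, 1, unit_id="B")])

    def test_routine_only_activity_rejected_in_campaign(self):
        with pytest.raises(CostingError, match="estimating_demand"):
            _item(1.0, 1.0, activity=Activity.ESTIMATING_DEMAND)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([a for a in Activity if a is not Activity.ESTIMATING_DEMAND]),
                st.sampled_from(list(CostType)),
                st.floats(min_value=0.0, max_value=1e6),
                st.booleans(),
            ),
            max_size=12,
        )
    )
    @settings(max_examples=40, derandomize=True)
    def test_additive_over_disjoint_item_sets(self, rows):
        items = [
            _item(1.0, cost, opportunity=flag, activity=act, cost_type=ct)
            for act, ct, cost, flag in rows
        ]
        half = len(items) // 2
        whole = unit_cost_matrix(items, context=Context.CAMPAIGN, unit_id="F001")
        a = unit_cost_matrix(items[:half], context=Context.CAMPAIGN, unit_id="F001")
        b = unit_cost_matrix(items[half:], context=Context.CAMPAIGN, unit_id="F001")
        combined = a + b
        np.testing.assert_allclose(
            combined.financial.to_numpy(), whole.financial.to_numpy(), rtol=1e-12
        )
        np.testing.assert_allclose(
            combined.economic.to_numpy(), whole.economic.to_numpy(), rtol=1e-12
        )
        # economic dominates financial cell-wise
        assert (whole.economic.to_numpy() >= whole.financial.to_numpy() - 1e-12).all()
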