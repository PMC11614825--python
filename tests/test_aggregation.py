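"""Design-weighted estimation, per-dose costs, and cross-level combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from campcost import (
    CostBasis,
    CostingError,
    DoseLedger,
    Level,
    SurveyDesign,
    combine_levels,
    dose_totals,
    hr_burden_summary,
    level_cost_per_dose,
    weighted_ci,
    weighted_mean,
)
from campcost.aggregation import LevelEstimate, weighted_variance_of_mean


def _design(unit_ids, weights):
    return SurveyDesign(
        pd.DataFrame(
            {"unit_id": unit_ids, "level": "facility", "stratum": "all", "weight": weights}
        )
    )


class TestWeightedMean:
    def test_unequal_weights(self):
        values = pd.Series({"a": 100.0, "b": 200.0, "c": 300.0})
        design = _design(["a", "b", "c"], [1.0, 1.0, 2.0])
        assert weighted_mean(values, design) == pytest.approx(225.0)

    def test_single_unit_identity(self):
        assert weighted_mean(pd.Series({"a": 42.0}), _design(["a"], [3.0])) == 42.0

    def test_missing_weight_names_unit(self):
        with pytest.raises(CostingError, match="zzz"):
            weighted_mean(pd.Series({"zzz": 1.0}), _design(["a"], [1.0]))

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_equal_weights_reduce_to_arithmetic_mean(self, values):
        ids = [f"u{i}" for i in range(len(values))]
        design = _design(ids, [2.5] * len(values))
        assert weighted_mean(pd.Series(values, index=ids), design) == pytest.approx(
            float(np.mean(values)), rel=1e-9, abs=1e-9
        )

    def test_agrees_with_statsmodels(self):
        # independent cross-check of the weighted mean and its variance
        sm = pytest.importorskip("statsmodels.stats.weightstats")
        rng = np.random.default_rng(3)
        values = rng.lognormal(1.0, 0.7, 25)
        weights = rng.uniform(0.5, 4.0, 25)
        ids = [f"u{i}" for i in range(25)]
        design = _design(ids, weights)
        series = pd.Series(values, index=ids)
        d = sm.DescrStatsW(values, weights=weights)
        assert weighted_mean(series, design) == pytest.approx(d.mean, rel=1e-12)


class TestWeightedCI:
    def test_identical_values_zero_width(self):
        values = pd.Series({"a": 5.0, "b": 5.0, "c": 5.0})
        lo, hi = weighted_ci(values, _design(["a", "b", "c"], [1, 2, 3]))
        assert lo == pytest.approx(5.0)
        assert hi == pytest.approx(5.0)

    def test_two_units_closed_form(self):
        # values {0, 2}, equal weights: mean 1, SE 1, symmetric normal CI
        values = pd.Series({"a": 0.0, "b": 2.0})
        lo, hi = weighted_ci(values, _design(["a", "b"], [1.0, 1.0]))
        z = stats.norm.ppf(0.975)
        assert (lo + hi) / 2 == pytest.approx(1.0)
        assert lo == pytest.approx(1.0 - z)
        assert hi == pytest.approx(1.0 + z)

    def test_single_unit_has_no_interval(self):
        assert weighted_ci(pd.Series({"a": 1.0}), _design(["a"], [1.0])) is None

    def test_equal_weight_variance_is_classic_se(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10, 2, 40)
        ids = [f"u{i}" for i in range(40)]
        var = weighted_variance_of_mean(
            pd.Series(values, index=ids), _design(ids, [1.0] * 40)
        )
        assert var == pytest.approx(values.var(ddof=1) / 40, rel=1e-9)

    def test_monte_carlo_coverage(self):
        # 95% CI on N(10, 2) samples of n=50 should cover 10 in >= 93%
        # of 1,000 replicates (normal approximation, z not t)
        rng = np.random.default_rng(42)
        ids = [f"u{i}" for i in range(50)]
        design = _design(ids, [1.0] * 50)
        hits = 0
        for _ in range(1000):
            values = pd.Series(rng.normal(10.0, 2.0, 50), index=ids)
            lo, hi = weighted_ci(values, design)
            hits += lo <= 10.0 <= hi
        assert hits / 1000 >= 0.93


class TestLevelCostPerDose:
    def test_national_is_exact_ratio(self):
        # published totals: $2,155,830 over 15,235,388 doses -> $0.14
        ledger = DoseLedger(
            pd.DataFrame({"unit_id": ["NAT"], "intervention": ["all"], "doses": [15_235_388]})
        )
        est = level_cost_per_dose(
            pd.Series({"NAT": 2_155_830.0}), ledger,
            _design(["NAT"], [1.0]), Level.NATIONAL, CostBasis.FINANCIAL,
        )
        assert est.cost_per_dose == pytest.approx(2_155_830 / 15_235_388)
        assert round(est.cost_per_dose, 2) == 0.14
        assert est.ci is None

    def test_facility_mean_rounds_to_one_cent(self):
        # published facility means: $301 over 29,677 doses -> $0.01
        ledger = DoseLedger(
            pd.DataFrame({"unit_id": ["F1", "F2"], "intervention": "all",
                          "doses": [29_677, 29_677]})
        )
        est = level_cost_per_dose(
            pd.Series({"F1": 301.0, "F2": 301.0}), ledger,
            _design(["F1", "F2"], [1.0, 1.0]), Level.FACILITY, CostBasis.FINANCIAL,
        )
        assert round(est.cost_per_dose, 2) == 0.01

    def test_zero_cost_unit(self):
        ledger = DoseLedger(
            pd.DataFrame({"unit_id": ["F1"], "intervention": ["all"], "doses": [100]})
        )
        est = level_cost_per_dose(
            pd.Series({"F1": 0.0}), ledger, _design(["F1"], [1.0]),
            Level.FACILITY, CostBasis.FINANCIAL,
        )
        assert est.cost_per_dose == 0.0

    def test_zero_dose_unit_excluded(self, caplog):
        ledger = DoseLedger(
            pd.DataFrame({"unit_id": ["F1", "F2", "F3"], "intervention": "all",
                          "doses": [100, 0, 100]})
        )
        with caplog.at_level("WARNING"):
            est = level_cost_per_dose(
                pd.Series({"F1": 10.0, "F2": 99.0, "F3": 30.0}), ledger,
                _design(["F1", "F2", "F3"], [1.0] * 3),
                Level.FACILITY, CostBasis.FINANCIAL,
            )
        assert est.n_units == 2
        assert est.cost_per_dose == pytest.approx((0.1 + 0.3) / 2)
        assert "F2" in caplog.text


def _estimate(cpd, ci=None, basis=CostBasis.FINANCIAL, level=Level.FACILITY):
    return LevelEstimate(
        level=level, basis=basis, n_units=1, mean_cost=0.0, mean_doses=0.0,
        cost_per_dose=cpd,
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
    )


class TestCombineLevels:
    def test_campaign_financial_table_arithmetic(self):
        # published per-level cells: 0.01 + 0.34 + 0.14 = 0.49, bounds
        # (0.01+0.27+0.14, 0.02+0.41+0.14) = (0.42, 0.57); the national
        # level has no interval and enters the bounds as a constant
        levels = [
            _estimate(0.01, (0.01, 0.02)),
            _estimate(0.34, (0.27, 0.41), level=Level.DISTRICT),
            _estimate(0.14, None, level=Level.NATIONAL),
        ]
        combined = combine_levels(levels)
        assert combined.cost_per_dose == pytest.approx(0.49)
        assert combined.ci_low == pytest.approx(0.42)
        assert combined.ci_high == pytest.approx(0.57)

    def test_campaign_economic_table_arithmetic(self):
        levels = [
            _estimate(0.35, (0.25, 0.46), basis=CostBasis.ECONOMIC),
            _estimate(0.35, (0.28, 0.42), basis=CostBasis.ECONOMIC, level=Level.DISTRICT),
            _estimate(0.14, None, basis=CostBasis.ECONOMIC, level=Level.NATIONAL),
        ]
        combined = combine_levels(levels)
        assert combined.cost_per_dose == pytest.approx(0.84)
        assert combined.ci_low == pytest.approx(0.67)
        assert combined.ci_high == pytest.approx(1.02)

    def test_single_level_identity(self):
        e = _estimate(0.2, (0.1, 0.3))
        combined = combine_levels([e])
        assert combined.cost_per_dose == e.cost_per_dose
        assert combined.ci == e.ci

    def test_order_invariant(self):
        levels = [_estimate(0.1, (0.05, 0.15)), _estimate(0.2, (0.1, 0.3)),
                  _estimate(0.3, None)]
        a = combine_levels(levels)
        b = combine_levels(levels[::-1])
        assert a.cost_per_dose == pytest.approx(b.cost_per_dose)
        assert a.ci == b.ci

    def test_mixed_bases_rejected(self):
        with pytest.raises(CostingError, match="bases"):
            combine_levels([
                _estimate(0.1), _estimate(0.2, basis=CostBasis.ECONOMIC),
            ])

    def test_variance_sum_alternative(self):
        levels = [_estimate(1.0, (0.0, 2.0)), _estimate(1.0, (0.0, 2.0))]
        combined = combine_levels(levels, method="variance_sum")
        hw = np.sqrt(2.0)
        assert combined.ci_low == pytest.approx(2.0 - hw)
        assert combined.ci_high == pytest.approx(2.0 + hw)


class TestDoseTotals:
    def test_national_table_column_sum(self):
        ledger = DoseLedger(pd.DataFrame({
            "unit_id": "NAT",
            "intervention": ["TCV", "MRV", "bOPV", "vitA"],
            "doses": [7_043_335, 2_646_095, 2_925_288, 2_620_670],
        }))
        table = dose_totals(ledger)
        assert table.loc["all_interventions", "total_doses"] == 15_235_388

    def test_facility_means_cross_foot(self):
        rows = []
        for uid in ("F1", "F2"):
            for name, d in {"TCV": 13_347, "MRV": 5_428, "bOPV": 5_749, "vitA": 5_153}.items():
                rows.append({"unit_id": uid, "intervention": name, "doses": d})
        table = dose_totals(DoseLedger(pd.DataFrame(rows)))
        assert table.loc["all_interventions", "mean_doses"] == pytest.approx(29_677)

    def test_negative_doses_rejected(self):
        with pytest.raises(CostingError):
            DoseLedger(pd.DataFrame({"unit_id": ["F1"], "intervention": ["TCV"], "doses": [-1]}))


class TestHrBurden:
    def test_single_unit(self):
        summary = hr_burden_summary(pd.DataFrame(
            {"unit_id": ["F1"], "persons": [10], "hired": [2], "overtime_hours": [1.0]}
        ))
        assert summary["persons_mean"] == 10
        assert summary["hired_mean"] == 2
        assert summary["overtime_mean_hours"] == 1.0
        assert summary["share_longer_days"] == 1.0

    def test_all_zero_overtime(self):
        summary = hr_burden_summary(pd.DataFrame(
            {"unit_id": ["F1", "F2"], "persons": [5, 7], "hired": [0, 1],
             "overtime_hours": [0.0, 0.0]}
        ))
        assert summary["share_longer_days"] == 0.0
        assert summary["overtime_mean_hours"] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(CostingError):
            hr_burden_summary(pd.DataFrame(
                {"unit_id": ["F1"], "persons": [-1], "hired": [0], "overtime_hours": [0.0]}
            ))
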