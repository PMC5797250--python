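"""Profit model, downside risk, factorial counting and strategy optimisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropskill.crop import CropDesign
from cropskill.design_value import (
    EconParams,
    StrategyProfile,
    count_crop_year_simulations,
    downside_risk,
    optimize_static,
    perfect_knowledge,
    profit,
    select_forecast_designs,
    static_profile,
    value_report,
)
from cropskill.errors import InputError, OptimizationError


class TestProfit:
    def test_failed_crop_loses_fixed_cost(self):
        assert profit(0.0, True, 50.0) == pytest.approx(-161.0)

    def test_harvested_worked_example(self):
        # 4 t x 254 - 1% insurance - 211 fixed = 794.84
        assert profit(4.0, False, 50.0) == pytest.approx(794.84)

    def test_incremental_nitrogen_cost(self):
        base = profit(4.0, False, 50.0)
        extra = profit(4.0, False, 100.0)
        assert base - extra == pytest.approx(0.30 * 50 / 0.46)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_linear_in_yield(self, y, dy):
        econ = EconParams()
        slope = (profit(y + dy, False, 50.0) - profit(y, False, 50.0)) / dy
        assert slope == pytest.approx(econ.price * (1 - econ.insurance_rate))

    def test_negative_yield_rejected(self):
        with pytest.raises(InputError):
            profit(-1.0, False, 50.0)


class TestDownsideRisk:
    @pytest.mark.parametrize(
        "profits, expect",
        [
            ([700.0, 800.0], 0.0),
            ([500.0, 700.0, 650.0, 400.0], 50.0),
            ([600.0, 600.0, 600.0], 0.0),  # strict inequality
        ],
    )
    def test_cases(self, profits, expect):
        assert downside_risk(profits, 600.0) == pytest.approx(expect)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            downside_risk([], 600.0)


class TestCounting:
    def test_published_configuration(self):
        cfg = {
            "locations": list(range(4)),
            "windows": ["Sep", "Oct", "Nov", "Dec", "Jan"],
            "soils": ["high", "medium", "low"],
            "isw": [0.2, 0.4, 0.6, 0.8],
            "row_configs": ["solid", "single_skip"],
            "densities": [3.5, 5, 6.5, 8],
            "n_rates": [50, 100, 150],
            "maturities": ["early", "medium", "late"],
            "tillering": ["none", "medium", "high"],
            "n_years": 34,
            "n_traces": 100,
        }
        assert count_crop_year_simulations(cfg) == 176_256_000

    def test_singletons(self):
        assert count_crop_year_simulations(
            {"a": [1], "b": [2], "n_years": 1, "n_traces": 1}
        ) == 1

    def test_small_product(self):
        assert count_crop_year_simulations(
            {"a": [1, 2], "b": [3, 4], "n_years": 3, "n_traces": 1}
        ) == 12

    def test_empty_factor_rejected(self):
        with pytest.raises(InputError):
            count_crop_year_simulations({"a": [], "n_years": 1, "n_traces": 1})


def random_instance(rng, n_designs=100, n_years=20):
    designs = [
        CropDesign(
            maturity=str(rng.choice(["early", "medium", "late"])),
            tillering=str(rng.choice(["none", "medium", "high"])),
            density=float(rng.uniform(2, 10)),
            row_config=str(rng.choice(["solid", "single_skip"])),
            n_rate=float(rng.uniform(40, 160)),
        )
        for _ in range(n_designs)
    ]
    ids = [d.design_id for d in designs]
    years = list(range(2000, 2000 + n_years))
    mat = pd.DataFrame(
        rng.normal(800, 250, (n_designs, n_years)), index=ids, columns=years
    )
    return designs, mat


class TestOptimizeStatic:
    def test_two_design_toy(self):
        designs = [CropDesign(n_rate=50.0), CropDesign(n_rate=100.0)]
        mat = pd.DataFrame(
            [[100.0, 200.0], [300.0, 400.0]],
            index=[d.design_id for d in designs],
            columns=[2000, 2001],
        )
        prof = optimize_static(mat, designs)
        assert prof.design_by_year[2000] == designs[1].design_id
        assert prof.mean_profit == pytest.approx(350.0)

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        designs, mat = random_instance(rng)
        prof = optimize_static(mat, designs)
        # independent oracle: explicit loop over candidate means
        best, best_mean = None, -np.inf
        for d in designs:
            m = mat.loc[d.design_id].mean()
            if m > best_mean:
                best, best_mean = d.design_id, m
        assert prof.design_by_year[2000] == best
        assert prof.mean_profit == pytest.approx(best_mean)

    def test_dominated_design_never_changes_result(self):
        rng = np.random.default_rng(43)
        designs, mat = random_instance(rng, n_designs=20)
        prof = optimize_static(mat, designs)
        dominated = CropDesign(density=9.9, n_rate=160.0)
        mat2 = pd.concat(
            [mat, pd.DataFrame(mat.min().to_numpy()[None, :] - 100.0,
                               index=[dominated.design_id], columns=mat.columns)]
        )
        prof2 = optimize_static(mat2, designs + [dominated])
        assert prof2.design_by_year == prof.design_by_year

    def test_empty_candidates_rejected(self):
        with pytest.raises(OptimizationError):
            optimize_static(pd.DataFrame(), [])


class TestPerfectKnowledge:
    def test_single_design_equals_farmer(self):
        d = CropDesign()
        mat = pd.DataFrame(
            [[100.0, 300.0]], index=[d.design_id], columns=[2000, 2001]
        )
        pk = perfect_knowledge(mat, [d])
        farmer = static_profile(mat, d)
        pd.testing.assert_series_equal(pk.profits, farmer.profits, check_names=False)

    def test_pointwise_dominates_static(self):
        rng = np.random.default_rng(44)
        designs, mat = random_instance(rng, n_designs=30)
        pk = perfect_knowledge(mat, designs)
        stat = optimize_static(mat, designs)
        for y in mat.columns:
            assert pk.profits[y] >= stat.profits[y] - 1e-9

    def test_equals_per_year_argmax_oracle(self):
        rng = np.random.default_rng(45)
        designs, mat = random_instance(rng, n_designs=25, n_years=8)
        pk = perfect_knowledge(mat, designs)
        for y in mat.columns:
            assert pk.profits[y] == pytest.approx(mat[y].max())


class TestForecastSelection:
    def test_low_skill_designs_never_selected(self):
        designs = [CropDesign(n_rate=50.0), CropDesign(n_rate=100.0)]
        ids = [d.design_id for d in designs]
        obs = pd.DataFrame([[100.0, 100], [90.0, 90]], index=ids, columns=[2000, 2001])
        # the filtered-out design has the best ensemble-mean profit
        ens = pd.DataFrame([[50.0, 50], [999.0, 999]], index=ids, columns=[2000, 2001])
        prof = select_forecast_designs(
            obs, ens, {ids[0]: 0.4, ids[1]: -0.2}, designs
        )
        assert set(prof.design_by_year.values()) == {ids[0]}

    def test_perfect_ensemble_recovers_perfect_knowledge(self):
        rng = np.random.default_rng(46)
        designs, mat = random_instance(rng, n_designs=15)
        prof = select_forecast_designs(
            mat, mat, {d.design_id: 1.0 for d in designs}, designs
        )
        pk = perfect_knowledge(mat, designs)
        assert prof.design_by_year == pk.design_by_year

    def test_empty_filter_falls_back_to_static(self):
        rng = np.random.default_rng(47)
        designs, mat = random_instance(rng, n_designs=10)
        prof = select_forecast_designs(
            mat, mat, {d.design_id: -0.5 for d in designs}, designs
        )
        stat = optimize_static(mat, designs)
        assert prof.fallback
        assert prof.design_by_year == stat.design_by_year


def constant_profile(strategy, mean, years=(2000,)):
    d = CropDesign()
    return StrategyProfile(
        strategy=strategy,
        design_by_year={y: d.design_id for y in years},
        profits=pd.Series({y: float(mean) for y in years}),
    )


class TestValueReport:
    @pytest.mark.parametrize(
        "farmer_mean, opt_mean, expect",
        [(1108.0, 1260.0, 152.0), (866.0, 1092.0, 226.0)],
    )
    def test_value_arithmetic(self, farmer_mean, opt_mean, expect):
        rep = value_report(
            constant_profile("farmer", farmer_mean),
            constant_profile("static_optimal", opt_mean),
            constant_profile("forecast_optimal", opt_mean),
            constant_profile("perfect_knowledge", opt_mean),
        )
        assert rep.value_optS == pytest.approx(expect)
        assert rep.value_optSCF == pytest.approx(0.0)

    def test_identities(self):
        rng = np.random.default_rng(48)
        designs, mat = random_instance(rng, n_designs=12)
        farmer = static_profile(mat, designs[0])
        stat = optimize_static(mat, designs)
        pk = perfect_knowledge(mat, designs)
        rep = value_report(farmer, stat, stat, pk)
        assert rep.value_optS == pytest.approx(
            stat.mean_profit - farmer.mean_profit, abs=1e-9
        )
        assert rep.value_PK == pytest.approx(
            pk.mean_profit - farmer.mean_profit, abs=1e-9
        )
        assert rep.value_PK >= rep.value_optS - 1e-9

    def test_mismatched_years_rejected(self):
        with pytest.raises(InputError):
            value_report(
                constant_profile("farmer", 100.0, years=(2000,)),
                constant_profile("static_optimal", 100.0, years=(2001,)),
                constant_profile("forecast_optimal", 100.0, years=(2001,)),
                constant_profile("perfect_knowledge", 100.0, years=(2001,)),
            )
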