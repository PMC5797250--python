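"""Probabilistic verification: Brier skill, percent consistent, reliability,
running skill and shift/dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropskill.climate import summarize_window_totals
from cropskill.errors import InputError, UndefinedMetricError
from cropskill.verification import (
    EventDefinition,
    brier_skill_score,
    event_outcomes,
    forecast_probability,
    percent_consistent,
    reliability_curve,
    running_skill,
    shift_dispersion,
    yield_event_skill,
)


def event_from_values(kind, values):
    return EventDefinition.from_window_stats(
        kind, summarize_window_totals(pd.Series(values, dtype=float))
    )


class TestEventOutcomes:
    def test_above_median_strict(self):
        ev = EventDefinition("above_median", median=25, t1_upper=15, t2_upper=35)
        assert event_outcomes([10, 20, 30, 40], ev).tolist() == [0, 0, 1, 1]
        assert event_outcomes([25.0], ev).tolist() == [0]  # tie falls below

    def test_tercile_one_counts_under_quantile_rule(self):
        # hand evaluation: type-7 1/3-quantile of [5..55] is 21.67, so
        # exactly the two smallest values fall in tercile 1
        vals = [5.0, 15, 25, 35, 45, 55]
        ev = event_from_values("tercile_1", vals)
        assert event_outcomes(vals, ev).sum() == 2

    def test_empty_series_rejected(self):
        ev = EventDefinition("above_median", median=0, t1_upper=0, t2_upper=0)
        with pytest.raises(InputError):
            event_outcomes([], ev)


class TestForecastProbability:
    def test_direct_count(self):
        ev = EventDefinition("above_median", median=55, t1_upper=40, t2_upper=75)
        assert forecast_probability([30, 50, 70, 90], ev) == pytest.approx(0.5)

    def test_all_above(self):
        ev = EventDefinition("above_median", median=5, t1_upper=3, t2_upper=8)
        assert forecast_probability([10, 20], ev) == 1.0

    @given(
        st.lists(st.floats(0, 500, allow_nan=False), min_size=2, max_size=40),
        st.floats(1, 400),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_complement(self, members, median):
        ev = EventDefinition(
            "above_median", median=median, t1_upper=median / 2, t2_upper=median * 1.5
        )
        p = forecast_probability(members, ev)
        below = np.mean(np.asarray(members) <= median)
        assert p + below == pytest.approx(1.0, abs=1e-12)


class TestBrierSkillScore:
    def test_climatology_reference_is_zero(self):
        probs = np.full(20, 0.5)
        outs = (np.arange(20) % 2).astype(float)
        assert brier_skill_score(probs, outs, 0.5)[2] == 0.0

    def test_perfect_forecast_is_one(self):
        outs = np.array([1.0, 0, 1, 0, 1])
        assert brier_skill_score(outs, outs, 0.5)[2] == 1.0

    def test_hand_case(self):
        bs, bs_ref, bss = brier_skill_score([0.8, 0.2], [1, 0], 0.5)
        assert bs == pytest.approx(0.04)
        assert bs_ref == pytest.approx(0.25)
        assert bss == pytest.approx(0.84)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(UndefinedMetricError):
            brier_skill_score([0.5, 0.5], [1, 1], 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 37
        p = rng.random(n)
        o = (rng.random(n) < 0.5).astype(float)
        bs, bs_ref, bss = brier_skill_score(p, o, 0.5)
        bs_loop = sum((pi - oi) ** 2 for pi, oi in zip(p, o)) / n
        assert abs(bs - bs_loop) < 1e-12

    def test_moving_probs_toward_outcomes_raises_skill(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        o = (rng.random(50) < 0.5).astype(float)
        closer = p + 0.3 * (o - p)
        assert (
            brier_skill_score(closer, o, 0.5)[2]
            > brier_skill_score(p, o, 0.5)[2]
        )


class TestPercentConsistent:
    def test_hand_count(self):
        # favoured A,A,B,B vs realised A,A,B,A -> 3 of 4
        pc = percent_consistent([0.9, 0.8, 0.2, 0.4], [1, 1, 0, 1], 0.5)
        assert pc == pytest.approx(75.0)

    def test_always_right(self):
        assert percent_consistent([1.0] * 5, [1] * 5, 0.5) == 100.0

    def test_base_rate_forecasts_excluded(self):
        with_half = percent_consistent([0.9, 0.5, 0.2], [1, 1, 0], 0.5)
        without = percent_consistent([0.9, 0.2], [1, 0], 0.5)
        assert with_half == without == 100.0

    def test_all_at_base_rate_undefined(self):
        with pytest.raises(UndefinedMetricError):
            percent_consistent([0.5, 0.5], [1, 0], 0.5)


class TestRunningSkill:
    def test_window_count(self):
        rng = np.random.default_rng(1)
        years = np.arange(1981, 2016)
        p = rng.random(35)
        o = (rng.random(35) < 0.5).astype(float)
        out = running_skill(p, o, years, window_years=30, metric="bss")
        assert len(out) == 6
        assert list(out.index) == list(range(2010, 2016))

    def test_matches_per_window_direct_calls(self):
        rng = np.random.default_rng(7)
        years = np.arange(1980, 2020)
        p = rng.random(40)
        o = (rng.random(40) < 0.5).astype(float)
        out = running_skill(p, o, years, window_years=30, metric="bss")
        for end, val in out.items():
            m = (years >= end - 29) & (years <= end)
            assert val == pytest.approx(
                brier_skill_score(p[m], o[m], 0.5)[2], abs=1e-12
            )

    def test_short_span_rejected(self):
        with pytest.raises(InputError):
            running_skill([0.5] * 5, [1, 0, 1, 0, 1], np.arange(5), window_years=30)


class TestReliability:
    def test_sharp_perfect_forecasts(self):
        p = np.array([0.0] * 20 + [1.0] * 20)
        o = np.array([0.0] * 20 + [1.0] * 20)
        rel = reliability_curve(p, o)
        assert rel.slope_b == pytest.approx(1.0)
        assert rel.rmse == pytest.approx(0.0, abs=1e-12)
        assert rel.sharpness_histogram.sum() == rel.n_forecasts == 40

    def test_calibrated_bernoulli_generator(self):
        """2000 forecasts with outcomes drawn at the issued probability:
        the reliability regression slope is ~1."""
        rng = np.random.default_rng(11)
        p = rng.random(2000)
        o = (rng.random(2000) < p).astype(float)
        rel = reliability_curve(p, o)
        assert 0.9 <= rel.slope_b <= 1.1

    def test_single_bin_slope_undefined(self):
        with pytest.raises(UndefinedMetricError):
            reliability_curve(np.full(20, 0.55), np.ones(20))


class TestShiftDispersion:
    def test_identical_samples(self):
        amd, vr = shift_dispersion([1.0, 2, 3], [1.0, 2, 3])
        assert amd == 0.0 and vr == 1.0

    def test_pure_location_shift(self):
        base = np.array([10.0, 30, 50])
        amd, vr = shift_dispersion(base + 20, base)
        assert amd == pytest.approx(20.0)
        assert vr == pytest.approx(1.0)

    def test_hand_variance_ratio(self):
        amd, vr = shift_dispersion([100.0, 120, 140], [80.0, 120, 160])
        assert amd == pytest.approx(0.0)
        assert vr == pytest.approx(0.25)  # sample variances 400/1600

    def test_zero_climatological_variance(self):
        with pytest.raises(UndefinedMetricError):
            shift_dispersion([1.0, 2], [5.0, 5])


class TestYieldEventSkill:
    @staticmethod
    def make_records(rng, n_years=12, n_members=8, noise=1.0):
        rows = []
        obs = 2.0 + rng.gamma(2.0, 0.5, n_years)
        for i, y in enumerate(range(2000, 2000 + n_years)):
            rows.append(dict(soil="high", year=y, trace=0, **{"yield": obs[i]}))
            for m in range(1, n_members + 1):
                ym = obs[i] + noise * rng.normal()
                rows.append(
                    dict(soil="high", year=y, trace=m, **{"yield": max(ym, 0.0)})
                )
        return pd.DataFrame(rows)

    def test_perfect_members_give_bss_one(self):
        rng = np.random.default_rng(3)
        rec = self.make_records(rng, noise=0.0)
        out = yield_event_skill(rec, group_cols=["soil"])
        assert (out["BSS"] == 1.0).all()
        assert set(out["event"]) == {"above_median", "tercile_1", "tercile_3"}

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(4)
        rec = self.make_records(rng, noise=0.8)
        out1 = yield_event_skill(rec, group_cols=["soil"])
        shuffled = rec.sample(frac=1.0, random_state=9).reset_index(drop=True)
        out2 = yield_event_skill(shuffled, group_cols=["soil"])
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_member_years_rejected(self):
        rng = np.random.default_rng(5)
        rec = self.make_records(rng)
        rec = rec[~((rec["year"] == 2003) & (rec["trace"] > 0))]
        with pytest.raises(InputError):
            yield_event_skill(rec, group_cols=["soil"])
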