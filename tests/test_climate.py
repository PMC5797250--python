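"""Synthetic weather, ENSO index and ensemble hindcast generator checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from cropskill import (
    ClimateGenParams,
    compute_climatology,
    generate_daily_weather,
    generate_ensemble_forecast,
    generate_enso_index,
)
from cropskill.climate import (
    SUMMER_MONTHS,
    generate_member_season,
    read_met_file,
    read_weather_csv,
    summarize_window_totals,
    window_totals,
    write_weather_csv,
)
from cropskill.errors import CoverageError, ParameterError
from cropskill.verification import EventDefinition, forecast_probability


class TestEnsoIndex:
    def test_standardized_scale(self):
        enso = generate_enso_index(0.8, 100, seed=1)
        assert abs(enso.values.mean()) < 0.5
        assert abs(enso.values.std(ddof=0) - 10.0) < 0.5

    @pytest.mark.parametrize(
        "ar1, lo, hi", [(0.0, -0.1, 0.1), (0.9, 0.8, 0.95)]
    )
    def test_lag1_autocorrelation(self, ar1, lo, hi):
        enso = generate_enso_index(ar1, 100, seed=3)  # 1200 months
        x = enso.values.to_numpy()
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lo <= r <= hi

    def test_nonstationary_coefficient_rejected(self):
        with pytest.raises(ParameterError):
            generate_enso_index(1.0, 10, seed=0)


class TestDailyWeather:
    def test_deterministic_under_seed(self, params36):
        a = generate_daily_weather(params36, 3)
        b = generate_daily_weather(params36, 3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_no_wet_days_means_no_rain(self):
        p = ClimateGenParams(wet_day_prob_by_month=np.zeros(12), seed=0)
        obs = generate_daily_weather(p, 2)
        assert (obs.data["rain"] == 0).all()

    def test_series_invariants(self, obs36):
        d = obs36.data
        assert d.index.is_monotonic_increasing
        assert (d["rain"] >= 0).all()
        assert (d["maxt"] >= d["mint"]).all()
        assert (d["radn"] > 0).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ParameterError):
            ClimateGenParams(wet_day_prob_by_month=np.full(12, 1.5))

    def test_teleconnection_strength_recovered(self, long_climate):
        """Sep-Feb totals correlate with the seasonal-mean index at the
        configured strength (500-year Monte Carlo, +/- 0.1)."""
        p, enso, obs = long_climate
        tot = window_totals(obs, 9, 6)
        z = enso.standardized()
        years, zbar = [], []
        for y in tot.index:
            pers = [pd.Period(f"{y}-{m:02d}", freq="M") for m in (9, 10, 11, 12)]
            pers += [pd.Period(f"{y + 1}-{m:02d}", freq="M") for m in (1, 2)]
            if all(per in z.index for per in pers):
                years.append(y)
                zbar.append(float(z[pers].mean()))
        r = np.corrcoef(tot[years].to_numpy(), zbar)[0, 1]
        assert abs(r - 0.6) < 0.1

    def test_summer_fraction_recovered(self, long_climate):
        p, _, obs = long_climate
        by_month = obs.data["rain"].groupby(obs.data.index.month).sum()
        frac = by_month[list(SUMMER_MONTHS)].sum() / by_month.sum()
        assert abs(frac - p.summer_fraction) < 0.05

    def test_infeasible_teleconnection_rejected(self):
        enso = generate_enso_index(0.2, 5, seed=0)
        p = ClimateGenParams(teleconnection_strength=0.99, seed=0)
        with pytest.raises(ParameterError):
            generate_daily_weather(p, 5, enso)


class TestClimatology:
    def test_linear_interpolation_quantiles(self):
        stats = summarize_window_totals(
            pd.Series([10.0, 20, 30, 40, 50, 60], index=range(2000, 2006))
        )
        assert stats.median == pytest.approx(35.0)
        assert stats.t1_upper == pytest.approx(26.6667, abs=1e-3)
        assert stats.t2_upper == pytest.approx(43.3333, abs=1e-3)

    def test_constant_totals_zero_cv(self):
        stats = summarize_window_totals(pd.Series([42.0, 42, 42]))
        assert stats.cv == 0.0

    def test_cv_uses_sample_sd(self):
        stats = summarize_window_totals(pd.Series([100.0, 200.0]))
        assert stats.mean == pytest.approx(150.0)
        assert stats.cv == pytest.approx(70.7107 / 150.0, abs=1e-4)

    def test_windows_and_ordering(self, obs36):
        clim = compute_climatology(obs36, [(9, 3), (10, 3)])
        for key, stats in clim.windows.items():
            assert stats.t1_upper <= stats.median <= stats.t2_upper
            assert stats.cv >= 0

    def test_short_reference_period_rejected(self, obs36):
        with pytest.raises(CoverageError):
            compute_climatology(obs36, [(9, 3)], reference_years=[1981, 1982])


class TestEnsembleForecast:
    def test_perfect_skill_members_equal_observation(self, obs36, params36):
        fc = generate_ensemble_forecast(
            obs36, "1990-10-01", 1.0, n_members=9, params=params36, seed=1
        )
        tot = window_totals(obs36, 10, 3)
        assert np.allclose(fc.totals, tot[1990])
        obs_slice = obs36.slice(pd.Timestamp("1990-10-01"), pd.Timestamp("1991-01-01"))
        for m in fc.members:
            pd.testing.assert_frame_equal(m, obs_slice)
        fc.validate()

    def test_member_totals_equal_trace_sums(self, obs36, params36):
        fc = generate_ensemble_forecast(
            obs36, "1995-09-01", 0.6, n_members=11, params=params36, seed=2
        )
        fc.validate()  # asserts totals == per-member rain sums
        assert fc.n_members == 11

    def test_no_skill_matches_climatology(self, obs36, params36):
        """At rho=0 the ensemble reproduces the climatological distribution:
        mean VR near 1 and mean AMD small relative to the climatological sd."""
        tot = window_totals(obs36, 10, 3)
        vrs, amds = [], []
        for y in range(1981, 2016):
            fc = generate_ensemble_forecast(
                obs36, f"{y}-10-01", 0.0, n_members=99, params=params36,
                seed=y, include_traces=False, totals=tot,
            )
            vrs.append(fc.totals.var(ddof=1) / tot.var(ddof=1))
            amds.append(abs(fc.totals.mean() - tot.mean()))
        assert abs(np.mean(vrs) - 1.0) < 0.15
        assert np.mean(amds) < 0.3 * tot.std(ddof=1)

    def test_ensemble_mean_correlation_tracks_skill(self, long_climate):
        """corr(ensemble-mean total, realized total) ~ rho over 200 issues."""
        p, _, obs = long_climate
        rho = 0.7
        tot = window_totals(obs, 10, 3)
        years = list(tot.index[:200])
        em, re = [], []
        for y in years:
            fc = generate_ensemble_forecast(
                obs, f"{y}-10-01", rho, n_members=99, params=p,
                seed=y, include_traces=False, totals=tot,
            )
            em.append(fc.totals.mean())
            re.append(tot[y])
        r = np.corrcoef(em, re)[0, 1]
        assert abs(r - rho) < 0.1

    @pytest.mark.parametrize("rho", [0.0, 0.5, 1.0])
    def test_calibration_binomial_bounds(self, long_climate, rho):
        """Issued above-median probabilities are reliable: per 0.1-bin the
        observed frequency lies inside the 99% binomial band around the bin
        mean probability (>= 300 issues)."""
        p, _, obs = long_climate
        tot = window_totals(obs, 11, 3)
        clim_stats = summarize_window_totals(tot)
        ev = EventDefinition.from_window_stats("above_median", clim_stats)
        years = list(tot.index[:400])
        probs, outs = [], []
        for y in years:
            fc = generate_ensemble_forecast(
                obs, f"{y}-11-01", rho, n_members=99, params=p,
                seed=1000 + y, include_traces=False, totals=tot,
            )
            probs.append(forecast_probability(fc.totals, ev))
            outs.append(int(tot[y] > clim_stats.median))
        probs, outs = np.array(probs), np.array(outs)
        edges = np.linspace(0, 1, 11)
        idx = np.clip(np.digitize(probs, edges[1:-1]), 0, 9)
        for b in range(10):
            sel = idx == b
            n = int(sel.sum())
            if n < 5:
                continue
            pbar = probs[sel].mean()
            lo = binom.ppf(0.005, n, pbar) / n
            hi = binom.ppf(0.995, n, pbar) / n
            assert lo <= outs[sel].mean() <= hi, f"bin {b}: rho={rho}"

    def test_window_not_covered(self, obs36, params36):
        with pytest.raises(CoverageError):
            generate_ensemble_forecast(
                obs36, "2016-12-01", 0.5, n_members=5, params=params36, seed=0
            )

    def test_member_season_concatenates_segments(self, obs36, params36):
        seasons = generate_member_season(
            obs36, "1990-10-01", 0.5, n_members=3, params=params36, seed=4
        )
        assert len(seasons) == 3
        for s in seasons:
            assert s.index[0] == pd.Timestamp("1990-10-01")
            assert s.index[-1] == pd.Timestamp("1991-03-31")
            assert s.index.is_monotonic_increasing and not s.index.has_duplicates


class TestWeatherIO:
    def test_csv_round_trip(self, obs36, tmp_path):
        path = tmp_path / "w.csv"
        small = obs36.data.iloc[:400]
        series = type(obs36)(site_id="Dalby", data=small)
        write_weather_csv(series, path, seed=5)
        back = read_weather_csv(path)
        assert back.site_id == "Dalby"
        pd.testing.assert_frame_equal(
            back.data, small, check_exact=False, atol=1e-3, check_freq=False
        )

    def test_met_file_reader(self, tmp_path):
        path = tmp_path / "station.met"
        path.write_text(
            "station = toy\n"
            "year day radn maxt mint rain\n"
            "() () MJ/m2 C C mm\n"
            "1990 1 22.0 31.0 16.0 0.0\n"
            "1990 2 20.5 30.0 15.5 12.4\n"
            "1990 3 18.0 28.0 14.0 0.0\n"
        )
        s = read_met_file(path)
        assert len(s.data) == 3
        assert s.data.index[0] == pd.Timestamp("1990-01-01")
        assert s.data["rain"].iloc[1] == pytest.approx(12.4)
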