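"""Synthetic daily weather, ENSO-like index, and tunable-skill ensemble hindcasts.

This module stands in for the observational and hindcast archives a real
study of forecast value would assemble: multi-decade station weather
(rain, maxt, mint, radn), a persistent standardized ENSO-like index
teleconnected to seasonal rainfall, and 99-member ensemble rainfall
forecasts issued on the first of each month at lead 0 whose skill is a
single tunable parameter ``skill_rho`` spanning no-skill (0) to perfect
knowledge (1).

Rainfall occurrence follows a first-order two-state Markov chain with
monthly wet-day probabilities; wet-day amounts are gamma distributed.
The ENSO teleconnection enters multiplicatively through the monthly gamma
scale, calibrated so that the correlation between summer (Sep--Feb)
rainfall totals and the seasonal-mean index equals the configured
``teleconnection_strength``.

Ensemble forecasts are built in a Gaussian (normal-scores) space of window
totals. For each issue a latent predictable signal

    s = rho^2 * z_obs + rho * sqrt(1 - rho^2) * eta

is drawn (``eta`` one standard-normal per issue), and members are

    z_i = s + sqrt(1 - rho^2) * eps_i.

Members are therefore draws from the true conditional distribution of the
outcome given the signal, so the system is reliable (calibrated) by
construction at every ``rho``; the ensemble-mean total correlates with the
realized total at ``rho``; at ``rho = 0`` members reproduce climatology and
at ``rho = 1`` every member equals the realized observation exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import CoverageError, InputError, ParameterError

__all__ = [
    "DailyWeatherSeries",
    "ClimateGenParams",
    "EnsoIndexSeries",
    "EnsembleForecast",
    "WindowStats",
    "ClimatologySummary",
    "generate_enso_index",
    "generate_daily_weather",
    "generate_ensemble_forecast",
    "generate_member_season",
    "compute_climatology",
    "window_totals",
    "write_weather_csv",
    "read_weather_csv",
    "read_met_file",
]

WEATHER_COLUMNS = ["rain", "maxt", "mint", "radn"]

# Months counted as the summer (Sep-Feb) rainfall season, first month = Sep.
SUMMER_MONTHS = (9, 10, 11, 12, 1, 2)

# Within-season weights used to spread the summer / winter shares of the
# annual mean across calendar months (Jan..Dec order).
_MONTH_WEIGHTS_SUMMER = {9: 0.10, 10: 0.13, 11: 0.16, 12: 0.21, 1: 0.22, 2: 0.18}
_MONTH_WEIGHTS_WINTER = {3: 0.22, 4: 0.16, 5: 0.13, 6: 0.13, 7: 0.16, 8: 0.20}

_DAYS_IN_MONTH = np.array([31.0, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DailyWeatherSeries:
    """A dated, gap-free daily weather record for one site.

    ``data`` is indexed by a daily :class:`~pandas.DatetimeIndex` and has
    columns ``rain`` (mm), ``maxt``/``mint`` (deg C) and ``radn``
    (MJ m^-2 day^-1).
    """

    site_id: str
    data: pd.DataFrame

    def validate(self) -> "DailyWeatherSeries":
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise InputError("weather index must be a DatetimeIndex")
        if len(idx) == 0:
            raise InputError("empty weather series")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise InputError("dates must be strictly increasing")
        expected = pd.date_range(idx[0], idx[-1], freq="D")
        if len(expected) != len(idx) or not (expected == idx).all():
            raise InputError("dates must be gap-free daily")
        d = self.data
        if (d["rain"] < 0).any():
            raise InputError("rain must be >= 0")
        if (d["maxt"] < d["mint"]).any():
            raise InputError("maxt must be >= mint")
        if (d["radn"] <= 0).any():
            raise InputError("radn must be > 0")
        return self

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.data.index[-1]

    def slice(self, start, end) -> pd.DataFrame:
        """Return the daily rows in ``[start, end)``; error on partial coverage."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start < self.start or end - pd.Timedelta(days=1) > self.end:
            raise CoverageError(
                f"window [{start.date()}, {end.date()}) not covered by weather "
                f"series [{self.start.date()}, {self.end.date()}]"
            )
        return self.data.loc[start : end - pd.Timedelta(days=1)]


@dataclass
class ClimateGenParams:
    """Parameters of the synthetic daily weather generator.

    Monthly arrays are in calendar order (index 0 = January). The
    teleconnection strength is the target correlation between Sep-Feb
    rainfall totals and the seasonal-mean standardized index.
    """

    site_id: str = "synthetic"
    annual_rain_mean: float = 650.0
    summer_fraction: float = 0.65
    wet_day_prob_by_month: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.32, 0.30, 0.26, 0.18, 0.14, 0.12, 0.11, 0.11, 0.16, 0.22, 0.27, 0.31]
        )
    )
    rain_shape: float = 0.55
    rain_scale_by_month: np.ndarray | None = None  # derived if None
    wet_persistence: float = 0.35  # lag-1 occurrence correlation of the chain
    interannual_cv: float = 0.15  # lognormal year-level rainfall multiplier
    temp_harmonic: tuple[float, float, float] = (19.5, 7.5, 15.0)  # mean, amp, peak doy
    temp_daily_sd: float = 2.0
    diurnal_range_mean: float = 13.0
    diurnal_range_sd: float = 1.5
    radn_harmonic: tuple[float, float, float] = (20.0, 6.5, 15.0)
    radn_daily_sd: float = 2.5
    teleconnection_strength: float = 0.0
    start_year: int = 1981
    seed: int = 0

    def __post_init__(self):
        self.wet_day_prob_by_month = np.asarray(self.wet_day_prob_by_month, float)
        if self.rain_scale_by_month is None:
            self.rain_scale_by_month = self._derive_monthly_scales()
        self.rain_scale_by_month = np.asarray(self.rain_scale_by_month, float)
        self.validate()

    def _derive_monthly_scales(self) -> np.ndarray:
        """Gamma scales that hit annual_rain_mean with the configured
        summer/winter split under the monthly wet-day probabilities."""
        monthly_mean = np.empty(12)
        for m in range(1, 13):
            if m in _MONTH_WEIGHTS_SUMMER:
                share = self.summer_fraction * _MONTH_WEIGHTS_SUMMER[m]
            else:
                share = (1.0 - self.summer_fraction) * _MONTH_WEIGHTS_WINTER[m]
            monthly_mean[m - 1] = self.annual_rain_mean * share
        expected_wet = _DAYS_IN_MONTH * self.wet_day_prob_by_month * self.rain_shape
        return np.divide(
            monthly_mean,
            expected_wet,
            out=np.zeros(12),
            where=expected_wet > 0,
        )

    def monthly_mean_rain(self) -> np.ndarray:
        return (
            _DAYS_IN_MONTH
            * self.wet_day_prob_by_month
            * self.rain_shape
            * self.rain_scale_by_month
        )

    def validate(self) -> "ClimateGenParams":
        p = self.wet_day_prob_by_month
        if p.shape != (12,) or (p < 0).any() or (p > 1).any():
            raise ParameterError("wet_day_prob_by_month must be 12 values in [0,1]")
        if self.rain_shape <= 0 or (self.rain_scale_by_month < 0).any():
            raise ParameterError("gamma parameters must be > 0")
        if not -1.0 <= self.teleconnection_strength <= 1.0:
            raise ParameterError("|teleconnection_strength| must be <= 1")
        if not 0.0 <= self.wet_persistence < 1.0:
            raise ParameterError("wet_persistence must be in [0, 1)")
        if not 0.0 <= self.summer_fraction <= 1.0:
            raise ParameterError("summer_fraction must be in [0, 1]")
        if self.interannual_cv < 0:
            raise ParameterError("interannual_cv must be >= 0")
        return self

    def replace(self, **kw) -> "ClimateGenParams":
        return dataclasses.replace(self, **kw)


@dataclass
class EnsoIndexSeries:
    """Monthly standardized ENSO-like index on the SOI scale (mean 0, sd 10)."""

    values: pd.Series  # indexed by monthly PeriodIndex
    ar1_coeff: float

    def validate(self) -> "EnsoIndexSeries":
        if not isinstance(self.values.index, pd.PeriodIndex):
            raise InputError("index must be a monthly PeriodIndex")
        if self.values.index.freqstr not in ("M", "ME"):
            raise InputError("index must be monthly")
        if self.values.isna().any():
            raise InputError("index values must be finite")
        return self

    def value(self, year: int, month: int) -> float:
        try:
            return float(self.values[pd.Period(f"{year}-{month:02d}", freq="M")])
        except KeyError as exc:
            raise CoverageError(f"no index value for {year}-{month:02d}") from exc

    def standardized(self) -> pd.Series:
        """Index on a unit-variance scale (values / 10)."""
        return self.values / 10.0


@dataclass
class EnsembleForecast:
    """One forecast issue: 99 member daily traces for the 3-month window
    starting at the issue month, and their window rainfall totals (mm)."""

    site_id: str
    issue_date: pd.Timestamp
    skill_rho: float
    totals: np.ndarray
    members: list[pd.DataFrame] | None = None
    lead: int = 0
    window_months: int = 3

    @property
    def n_members(self) -> int:
        return len(self.totals)

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = self.issue_date
        return start, _add_months(start, self.window_months)

    def validate(self) -> "EnsembleForecast":
        if self.members is not None:
            if len(self.members) != len(self.totals):
                raise InputError("totals and member traces disagree in length")
            sums = np.array([float(m["rain"].sum()) for m in self.members])
            if not np.allclose(sums, self.totals, atol=1e-6):
                raise InputError("member totals must equal trace rainfall sums")
        return self


@dataclass
class WindowStats:
    """Climatological statistics for one 3-month (or N-month) window."""

    start_month: int
    n_months: int
    mean: float
    median: float
    t1_upper: float
    t2_upper: float
    cv: float
    totals: pd.Series  # per-year window totals, indexed by start year

    def validate(self) -> "WindowStats":
        if not self.t1_upper <= self.median <= self.t2_upper:
            raise InputError("tercile boundaries must bracket the median")
        if self.cv < 0:
            raise InputError("CV must be >= 0")
        return self


@dataclass
class ClimatologySummary:
    """Per-window climatology over a reference period."""

    reference_years: list[int]
    windows: dict[tuple[int, int], WindowStats]

    def window(self, start_month: int, n_months: int = 3) -> WindowStats:
        try:
            return self.windows[(start_month, n_months)]
        except KeyError as exc:
            raise CoverageError(
                f"no climatology for window starting month {start_month}"
            ) from exc


# ---------------------------------------------------------------------------
# Calendar helpers
# ---------------------------------------------------------------------------


def _add_months(ts: pd.Timestamp, k: int) -> pd.Timestamp:
    y, m = divmod(ts.month - 1 + k, 12)
    return pd.Timestamp(year=ts.year + y, month=m + 1, day=1)


def window_totals(
    obs: DailyWeatherSeries, start_month: int, n_months: int = 3
) -> pd.Series:
    """Per-year rainfall totals for the window of ``n_months`` starting at
    ``start_month``; labelled by the start year; partially covered years
    are dropped."""
    totals = {}
    for year in range(obs.start.year, obs.end.year + 1):
        w0 = pd.Timestamp(year=year, month=start_month, day=1)
        w1 = _add_months(w0, n_months)
        if w0 < obs.start or w1 - pd.Timedelta(days=1) > obs.end:
            continue
        totals[year] = float(
            obs.data["rain"].loc[w0 : w1 - pd.Timedelta(days=1)].sum()
        )
    return pd.Series(totals, dtype=float)


# ---------------------------------------------------------------------------
# ENSO-like index
# ---------------------------------------------------------------------------


def generate_enso_index(
    ar1_coeff: float, n_years: int, seed: int, start_year: int = 1981
) -> EnsoIndexSeries:
    """Stationary AR(1) monthly index, standardized to mean 0 and sd 10.

    ``ar1_coeff`` is the month-to-month persistence; |ar1_coeff| < 1.
    """
    if not abs(ar1_coeff) < 1:
        raise ParameterError("|ar1_coeff| must be < 1")
    if n_years < 1:
        raise ParameterError("n_years must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = 12 * n_years
    x = np.empty(n)
    innov = rng.standard_normal(n)
    x[0] = innov[0]
    c = np.sqrt(1.0 - ar1_coeff**2)
    for t in range(1, n):
        x[t] = ar1_coeff * x[t - 1] + c * innov[t]
    x = (x - x.mean()) / x.std(ddof=0) * 10.0
    idx = pd.period_range(f"{start_year}-01", periods=n, freq="M")
    return EnsoIndexSeries(values=pd.Series(x, index=idx), ar1_coeff=ar1_coeff)


# ---------------------------------------------------------------------------
# Rainfall occurrence/amount core (vectorized across parallel series)
# ---------------------------------------------------------------------------


def _markov_gamma_rain(
    rng: np.random.Generator,
    month_of_day: np.ndarray,  # (n_days,) 1..12
    n_series: int,
    params: ClimateGenParams,
    scale_mult: np.ndarray | float = 1.0,  # broadcastable to (n_series, n_days)
) -> np.ndarray:
    """Daily rain for ``n_series`` parallel series sharing a calendar.

    Occurrence: two-state chain with stationary monthly probability pi and
    lag-1 correlation c: p(wet|wet) = pi + c(1-pi), p(wet|dry) = pi(1-c).
    Day 0 draws from the stationary probability. Amounts: gamma(shape) with
    monthly scale, optionally modulated by ``scale_mult``.
    """
    n_days = len(month_of_day)
    pi = params.wet_day_prob_by_month[month_of_day - 1]  # (n_days,)
    c = params.wet_persistence
    u = rng.random((n_series, n_days))
    wet = np.empty((n_series, n_days), dtype=bool)
    wet[:, 0] = u[:, 0] < pi[0]
    for d in range(1, n_days):
        p11 = pi[d] + c * (1.0 - pi[d])
        p01 = pi[d] * (1.0 - c)
        thresh = np.where(wet[:, d - 1], p11, p01)
        wet[:, d] = u[:, d] < thresh
    amounts = rng.gamma(params.rain_shape, 1.0, size=(n_series, n_days))
    scale = params.rain_scale_by_month[month_of_day - 1] * np.asarray(scale_mult)
    return np.where(wet, amounts * scale, 0.0)


def _temps_radn(
    rng: np.random.Generator, doy: np.ndarray, shape: tuple, params: ClimateGenParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """maxt, mint, radn arrays of ``shape`` (..., n_days) for day-of-year ``doy``."""
    tm, ta, tp = params.temp_harmonic
    rm, ra, rp = params.radn_harmonic
    phase = np.cos(2 * np.pi * (doy - tp) / 365.25)
    tmean = tm + ta * phase + rng.normal(0.0, params.temp_daily_sd, size=shape)
    half = 0.5 * np.maximum(
        2.0, rng.normal(params.diurnal_range_mean, params.diurnal_range_sd, size=shape)
    )
    radn = np.maximum(
        1.0,
        rm
        + ra * np.cos(2 * np.pi * (doy - rp) / 365.25)
        + rng.normal(0.0, params.radn_daily_sd, size=shape),
    )
    return tmean + half, tmean - half, radn


# ---------------------------------------------------------------------------
# Teleconnection calibration
# ---------------------------------------------------------------------------


def _season_month_positions(ar1: float):
    """Covariance pieces for the 6 consecutive Sep..Feb months of a
    unit-variance AR(1) index: Var(u), Cov(u, zbar), Var(zbar) where
    u = sum_m mu_m z_m and zbar is the seasonal-mean index."""
    lags = np.abs(np.subtract.outer(np.arange(6), np.arange(6)))
    return np.power(ar1, lags)


def _calibrate_teleconnection_k(
    params: ClimateGenParams, ar1: float, v_base: float
) -> float:
    """Multiplier strength k in (1 + k z_month) giving corr(Sep-Feb total,
    seasonal-mean index) = teleconnection_strength, from AR(1) covariances
    and the pilot-estimated unmodulated seasonal-total variance ``v_base``."""
    rho = params.teleconnection_strength
    if rho == 0.0:
        return 0.0
    mu = params.monthly_mean_rain()[[m - 1 for m in SUMMER_MONTHS]]
    cov = _season_month_positions(ar1)
    var_u = float(mu @ cov @ mu)
    cov_u_zbar = float(mu @ cov.sum(axis=1)) / 6.0
    var_zbar = float(cov.sum()) / 36.0
    cz = cov_u_zbar / np.sqrt(var_zbar)
    denom = cz**2 - rho**2 * var_u
    if denom <= 0:
        raise ParameterError(
            "teleconnection_strength exceeds the maximum achievable correlation "
            "for this index persistence; reduce |teleconnection_strength|"
        )
    return float(rho * np.sqrt(v_base / denom))


def _pilot_seasonal_variance(
    params: ClimateGenParams, seed_seq: np.random.SeedSequence, n_pilot: int = 400
) -> float:
    """Monte Carlo variance of unmodulated Sep-Feb totals (includes chain
    persistence and the interannual multiplier), on a dedicated substream."""
    rng = np.random.default_rng(seed_seq)
    # Sep..Feb of a non-leap-year layout
    months = np.concatenate(
        [np.full(n, m) for m, n in zip(SUMMER_MONTHS, (30, 31, 30, 31, 31, 28))]
    )
    mult = _interannual_multipliers(rng, params, n_pilot)[:, None]
    rain = _markov_gamma_rain(rng, months, n_pilot, params, scale_mult=mult)
    return float(rain.sum(axis=1).var(ddof=1))


def _interannual_multipliers(
    rng: np.random.Generator, params: ClimateGenParams, n_years: int
) -> np.ndarray:
    cv = params.interannual_cv
    if cv == 0:
        return np.ones(n_years)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_years)


# ---------------------------------------------------------------------------
# Daily weather generator
# ---------------------------------------------------------------------------


def generate_daily_weather(
    params: ClimateGenParams,
    n_years: int,
    enso: EnsoIndexSeries | None = None,
) -> DailyWeatherSeries:
    """Seeded synthetic daily weather for ``n_years`` calendar years starting
    at ``params.start_year``.

    Rain occurrence follows the monthly two-state chain, amounts are gamma,
    and when ``enso`` is supplied with nonzero ``teleconnection_strength``
    the monthly gamma scale is modulated by (1 + k z_month) with k
    calibrated so Sep-Feb totals correlate with the seasonal-mean index at
    the configured strength. Pure function of (params, enso, seed).
    """
    params.validate()
    if n_years < 1:
        raise ParameterError("n_years must be >= 1")
    if params.teleconnection_strength != 0.0 and enso is None:
        raise ParameterError("an ENSO index is required when teleconnection != 0")

    root = np.random.SeedSequence(params.seed)
    ss_pilot, ss_annual, ss_rain, ss_met = root.spawn(4)

    years = np.arange(params.start_year, params.start_year + n_years)
    # per-year calendar laid out as (n_years, 366) with a validity mask
    dates_by_year = [
        pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D") for y in years
    ]
    n_pad = 366
    month_mat = np.ones((n_years, n_pad), dtype=int)
    doy_mat = np.ones((n_years, n_pad), dtype=float)
    valid = np.zeros((n_years, n_pad), dtype=bool)
    for i, dr in enumerate(dates_by_year):
        month_mat[i, : len(dr)] = dr.month
        doy_mat[i, : len(dr)] = dr.dayofyear
        valid[i, : len(dr)] = True

    # year-level multiplier and ENSO modulation of the monthly scale
    rng_annual = np.random.default_rng(ss_annual)
    mult = _interannual_multipliers(rng_annual, params, n_years)[:, None]
    k = 0.0
    if params.teleconnection_strength != 0.0:
        v_base = _pilot_seasonal_variance(params, ss_pilot)
        k = _calibrate_teleconnection_k(params, enso.ar1_coeff, v_base)
    scale_mult = np.broadcast_to(mult, (n_years, n_pad)).copy()
    if k != 0.0:
        z = enso.standardized()
        zmat = np.zeros((n_years, n_pad))
        for i, (y, dr) in enumerate(zip(years, dates_by_year)):
            per = pd.PeriodIndex(dr, freq="M")
            try:
                zmat[i, : len(dr)] = z[per].to_numpy()
            except KeyError as exc:
                raise CoverageError(
                    f"ENSO index does not cover year {y}"
                ) from exc
        scale_mult *= np.maximum(0.05, 1.0 + k * zmat)

    # the chain runs within each year; 1 Jan draws from the stationary
    # probability (documented boundary approximation). Years sharing a
    # calendar length are generated as one vectorized block.
    rng_rain = np.random.default_rng(ss_rain)
    rain_rows: list[np.ndarray | None] = [None] * n_years
    lengths = valid.sum(axis=1)
    for n_days_y in sorted(set(lengths)):
        rows = np.flatnonzero(lengths == n_days_y)
        months_g = month_mat[rows[0], :n_days_y]
        block = _markov_gamma_rain(
            rng_rain,
            months_g,
            len(rows),
            params,
            scale_mult=scale_mult[rows, :n_days_y],
        )
        for j, i in enumerate(rows):
            rain_rows[i] = block[j]
    rain = np.concatenate(rain_rows)

    rng_met = np.random.default_rng(ss_met)
    maxt_m, mint_m, radn_m = _temps_radn(
        rng_met, doy_mat, (n_years, n_pad), params
    )
    maxt = maxt_m[valid]
    mint = mint_m[valid]
    radn = radn_m[valid]

    index = pd.date_range(
        f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D"
    )
    data = pd.DataFrame(
        {"rain": rain, "maxt": maxt, "mint": mint, "radn": radn}, index=index
    )
    return DailyWeatherSeries(site_id=params.site_id, data=data).validate()


# ---------------------------------------------------------------------------
# Climatology
# ---------------------------------------------------------------------------


def compute_climatology(
    obs: DailyWeatherSeries,
    windows: Sequence[tuple[int, int]] = ((9, 3),),
    reference_years: Sequence[int] | None = None,
) -> ClimatologySummary:
    """Per-window mean, median, empirical terciles and CV over the
    reference period.

    ``windows`` is a sequence of (start_month, n_months). Terciles are the
    1/3 and 2/3 empirical quantiles under linear-interpolation (type-7)
    rules; CV uses the sample (n-1) standard deviation.
    """
    out: dict[tuple[int, int], WindowStats] = {}
    ref_used: list[int] | None = None
    for start_month, n_months in windows:
        totals = window_totals(obs, start_month, n_months)
        if reference_years is not None:
            totals = totals[totals.index.isin(list(reference_years))]
        if len(totals) < 3:
            raise CoverageError(
                f"reference period for window ({start_month},{n_months}) "
                f"has {len(totals)} years; >= 3 required"
            )
        out[(start_month, n_months)] = summarize_window_totals(
            totals, start_month, n_months
        )
        ref_used = sorted(totals.index.tolist())
    return ClimatologySummary(reference_years=ref_used or [], windows=out)


def summarize_window_totals(
    totals: pd.Series, start_month: int = 0, n_months: int = 3
) -> WindowStats:
    """WindowStats from per-year totals (shared by rainfall and yield
    climatologies)."""
    arr = totals.to_numpy(dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return WindowStats(
        start_month=start_month,
        n_months=n_months,
        mean=mean,
        median=float(np.quantile(arr, 0.5)),
        t1_upper=float(np.quantile(arr, 1.0 / 3.0)),
        t2_upper=float(np.quantile(arr, 2.0 / 3.0)),
        cv=sd / mean if mean > 0 else 0.0,
        totals=totals,
    ).validate()


# ---------------------------------------------------------------------------
# Ensemble hindcasts (normal-scores signal-plus-noise construction)
# ---------------------------------------------------------------------------


def _normal_scores(totals: pd.Series) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Gaussian anamorphosis of window totals.

    Returns (sorted z nodes, sorted totals, per-year z) where z nodes are
    Phi^-1((rank - 0.5)/n) with average ranks for ties.
    """
    from scipy.stats import rankdata

    arr = totals.to_numpy(dtype=float)
    n = len(arr)
    z = ndtri((rankdata(arr, method="average") - 0.5) / n)
    order = np.argsort(arr, kind="stable")
    zs, ts = z[order], arr[order]
    keep = np.concatenate([[True], np.diff(zs) > 0])
    return zs[keep], ts[keep], pd.Series(z, index=totals.index)


def _z_to_totals(z: np.ndarray, z_nodes: np.ndarray, t_nodes: np.ndarray) -> np.ndarray:
    """Map Gaussian scores back to rainfall totals by interpolating the
    empirical quantile function; tails clamp to the observed extremes."""
    if len(z_nodes) == 1:
        return np.full_like(np.asarray(z, float), t_nodes[0])
    return np.maximum(0.0, np.interp(z, z_nodes, t_nodes))


def _conditional_member_scores(
    rng: np.random.Generator, z_obs: float, rho: float, n_members: int
) -> np.ndarray:
    """Member Gaussian scores given the realized score and skill rho."""
    eta = rng.standard_normal()
    eps = rng.standard_normal(n_members)
    noise = np.sqrt(max(0.0, 1.0 - rho**2))
    s = rho**2 * z_obs + rho * noise * eta
    return s + noise * eps


def _member_daily_traces(
    rng: np.random.Generator,
    obs: DailyWeatherSeries,
    w0: pd.Timestamp,
    w1: pd.Timestamp,
    member_totals: np.ndarray,
    params: ClimateGenParams,
) -> list[pd.DataFrame]:
    """Fresh synthetic daily traces over [w0, w1), each rescaled so its
    rainfall sums to the member total; temperatures and radiation are
    synthetic (rainfall is the only skill-bearing variable)."""
    days = pd.date_range(w0, w1 - pd.Timedelta(days=1), freq="D")
    n_members = len(member_totals)
    rain = _markov_gamma_rain(rng, days.month.to_numpy(), n_members, params)
    sums = rain.sum(axis=1)
    for i in range(n_members):
        if sums[i] > 0:
            rain[i] *= member_totals[i] / sums[i]
        elif member_totals[i] > 0:
            rain[i, len(days) // 2] = member_totals[i]
    doy = days.dayofyear.to_numpy()[None, :]
    maxt, mint, radn = _temps_radn(rng, doy, (n_members, len(days)), params)
    return [
        pd.DataFrame(
            {"rain": rain[i], "maxt": maxt[i], "mint": mint[i], "radn": radn[i]},
            index=days,
        )
        for i in range(n_members)
    ]


def generate_ensemble_forecast(
    obs: DailyWeatherSeries,
    issue_date,
    skill_rho: float,
    n_members: int = 99,
    params: ClimateGenParams | None = None,
    seed: int | None = None,
    include_traces: bool = True,
    window_months: int = 3,
    totals: pd.Series | None = None,
) -> EnsembleForecast:
    """A tunable-skill ensemble forecast issued on the 1st of a month at
    lead 0 for the following ``window_months``-month rainfall total.

    At ``skill_rho = 0`` member totals reproduce climatology; at
    ``skill_rho = 1`` every member equals the realized observation exactly
    (the member traces are then the observed daily slice). ``totals`` may
    pass precomputed per-year window totals to avoid recomputation in
    batch verification runs.
    """
    if not 0.0 <= skill_rho <= 1.0:
        raise ParameterError("skill_rho must be in [0, 1]")
    issue_date = pd.Timestamp(issue_date)
    if issue_date.day != 1:
        raise ParameterError("forecasts are issued on the 1st of a month")
    w0, w1 = issue_date, _add_months(issue_date, window_months)
    obs.slice(w0, w1)  # raises CoverageError if not covered
    if totals is None:
        totals = window_totals(obs, issue_date.month, window_months)
    target_year = issue_date.year
    if target_year not in totals.index:
        raise CoverageError(f"no observed total for issue year {target_year}")

    rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    params = params or ClimateGenParams(site_id=obs.site_id)

    if np.isclose(skill_rho, 1.0):
        obs_total = float(totals[target_year])
        member_totals = np.full(n_members, obs_total)
        members = None
        if include_traces:
            obs_slice = obs.slice(w0, w1)
            members = [obs_slice.copy() for _ in range(n_members)]
        return EnsembleForecast(
            site_id=obs.site_id,
            issue_date=issue_date,
            skill_rho=skill_rho,
            totals=member_totals,
            members=members,
            window_months=window_months,
        )

    z_nodes, t_nodes, z_by_year = _normal_scores(totals)
    z_obs = float(z_by_year[target_year])
    z_members = _conditional_member_scores(rng, z_obs, skill_rho, n_members)
    member_totals = _z_to_totals(z_members, z_nodes, t_nodes)
    members = None
    if include_traces:
        members = _member_daily_traces(rng, obs, w0, w1, member_totals, params)
    return EnsembleForecast(
        site_id=obs.site_id,
        issue_date=issue_date,
        skill_rho=skill_rho,
        totals=member_totals,
        members=members,
        window_months=window_months,
    )


def generate_member_season(
    obs: DailyWeatherSeries,
    issue_date,
    skill_rho: float,
    n_members: int = 99,
    params: ClimateGenParams | None = None,
    seed: int | None = None,
    n_segments: int = 2,
    segment_months: int = 3,
) -> list[pd.DataFrame]:
    """Member daily weather covering ``n_segments`` consecutive 3-month
    segments from the issue date (default 6 months), for driving the crop
    model.

    The first segment is the lead-0 forecast window; later segments are
    conditioned on their own observed totals at the same ``skill_rho``
    (emulating a long-range model run downscaled to daily weather). At
    ``skill_rho = 1`` the member season equals the observed weather
    exactly; at 0 every segment is climatological.
    """
    issue_date = pd.Timestamp(issue_date)
    params = params or ClimateGenParams(site_id=obs.site_id)
    seed_seq = np.random.SeedSequence(0 if seed is None else seed)
    seg_seeds = seed_seq.spawn(n_segments)
    pieces: list[list[pd.DataFrame]] = []
    for seg in range(n_segments):
        seg_issue = _add_months(issue_date, seg * segment_months)
        fc = generate_ensemble_forecast(
            obs,
            seg_issue,
            skill_rho,
            n_members=n_members,
            params=params,
            seed=int(seg_seeds[seg].generate_state(1)[0] % (2**31)),
            include_traces=True,
            window_months=segment_months,
        )
        pieces.append(fc.members)
    return [
        pd.concat([pieces[seg][i] for seg in range(n_segments)])
        for i in range(n_members)
    ]


def segment_seed(seed: int, segment: int, n_segments: int = 2) -> int:
    """Child seed of segment ``segment`` of an issue-level seed, shared by
    :func:`member_season_arrays` and batch ensemble-total generation so the
    lead-0 window of a member season reproduces the issued forecast."""
    seq = np.random.SeedSequence(seed).spawn(n_segments)[segment]
    return int(seq.generate_state(1)[0] % (2**31))


def member_season_arrays(
    obs: DailyWeatherSeries,
    issue_date,
    skill_rho: float,
    n_members: int,
    params: ClimateGenParams,
    seed: int,
    n_segments: int = 2,
    segment_months: int = 3,
    scores_cache: dict | None = None,
) -> dict[str, np.ndarray]:
    """Array fast path of :func:`generate_member_season` for batch crop runs.

    Returns ``{rain, maxt, mint, radn}`` arrays of shape (n_members,
    n_days) covering ``n_segments`` consecutive ``segment_months``-month
    segments from the issue date, each conditioned on its own observed
    total at ``skill_rho``. With the default 3-month segments, segment 0
    uses the same random draws as :func:`generate_ensemble_forecast` called
    with ``segment_seed(seed, 0)``, so its member totals equal the issued
    forecast totals. ``scores_cache`` (keyed by (start_month, n_months))
    memoises the normal-scores transform of each calendar window across
    issues.
    """
    issue = pd.Timestamp(issue_date)
    end = _add_months(issue, n_segments * segment_months)
    if np.isclose(skill_rho, 1.0):
        sl = obs.slice(issue, end)
        return {
            c: np.tile(sl[c].to_numpy(), (n_members, 1)) for c in WEATHER_COLUMNS
        }
    parts: dict[str, list[np.ndarray]] = {c: [] for c in WEATHER_COLUMNS}
    for seg in range(n_segments):
        w0 = _add_months(issue, seg * segment_months)
        w1 = _add_months(w0, segment_months)
        key = (w0.month, segment_months)
        cached = scores_cache.get(key) if scores_cache is not None else None
        if cached is None:
            totals = window_totals(obs, w0.month, segment_months)
            cached = _normal_scores(totals)
            if scores_cache is not None:
                scores_cache[key] = cached
        z_nodes, t_nodes, z_by_year = cached
        z_obs = float(z_by_year[w0.year])
        rng = np.random.default_rng(
            np.random.SeedSequence(segment_seed(seed, seg, n_segments))
        )
        z_members = _conditional_member_scores(rng, z_obs, skill_rho, n_members)
        member_totals = _z_to_totals(z_members, z_nodes, t_nodes)
        days = pd.date_range(w0, w1 - pd.Timedelta(days=1), freq="D")
        rain = _markov_gamma_rain(rng, days.month.to_numpy(), n_members, params)
        sums = rain.sum(axis=1)
        pos = sums > 0
        rain *= np.where(pos, member_totals / np.where(pos, sums, 1.0), 0.0)[:, None]
        need = (~pos) & (member_totals > 0)
        rain[need, len(days) // 2] = member_totals[need]
        doy = days.dayofyear.to_numpy()[None, :]
        maxt, mint, radn = _temps_radn(rng, doy, (n_members, len(days)), params)
        parts["rain"].append(rain)
        parts["maxt"].append(maxt)
        parts["mint"].append(mint)
        parts["radn"].append(radn)
    return {c: np.concatenate(parts[c], axis=1) for c in WEATHER_COLUMNS}


# ---------------------------------------------------------------------------
# Weather file I/O
# ---------------------------------------------------------------------------


def write_weather_csv(series: DailyWeatherSeries, path, seed: int | None = None):
    """CSV with header ``date,rain,maxt,mint,radn``; the generator seed is
    recorded in a leading ``#`` comment when supplied."""
    with open(path, "w") as fh:
        fh.write(f"# site={series.site_id}")
        if seed is not None:
            fh.write(f" seed={seed}")
        fh.write("\n")
        df = series.data.reset_index(names="date")
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(fh, index=False, float_format="%.4f")


def read_weather_csv(path, site_id: str | None = None) -> DailyWeatherSeries:
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    df = df.set_index("date")[WEATHER_COLUMNS].rename_axis(None)
    if site_id is None:
        site_id = _site_from_header(path) or "unknown"
    return DailyWeatherSeries(site_id=site_id, data=df).validate()


def _site_from_header(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("site="):
                return token[5:]
    return None


def read_met_file(path, site_id: str = "met") -> DailyWeatherSeries:
    """Whitespace-delimited met-style file with columns
    ``year day radn maxt mint rain`` (day = day of year)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="!",
        names=["year", "day", "radn", "maxt", "mint", "rain"],
        header=None,
        skiprows=_met_header_rows(path),
    )
    dates = pd.to_datetime(
        df["year"].astype(int).astype(str) + "-" + df["day"].astype(int).astype(str),
        format="%Y-%j",
    )
    data = df[WEATHER_COLUMNS].set_index(dates)
    return DailyWeatherSeries(site_id=site_id, data=data).validate()


def _met_header_rows(path) -> int:
    """Count leading non-numeric rows (site/units headers) in a met file."""
    n = 0
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if tok and not line.startswith("!"):
                try:
                    float(tok[0])
                    break
                except ValueError:
                    pass
            n += 1
    return n
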