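"""Transparent water-bucket sorghum yield proxy over the G x E x M factorial.

A deliberately simple, fully documented stand-in for a process-based crop
model. The soil is a single bucket of plant-available water capacity PAWC
(mm), filled to ``isw_frac`` x PAWC at sowing. Each day:

    runoff   = runoff_curve * max(rain - runoff_thresh, 0)
    SW      += rain - runoff            (overflow above PAWC drains away)
    soil_ev  = evap_coeff * SW / PAWC
    demand   = demand_coeff * radn * f(density) * f(tillering) * f(row)
    transp   = min(demand, kl * SW)     while thermal time < maturity target

Phenology is thermal time above a base temperature; the maturity class sets
the season-length target, with anthesis at a fixed fraction of it. Grain
fill must receive a minimum share of the season's water use: the effective
water supply is min(T_total, T_post / post_water_frac), so designs that
exhaust the bucket before anthesis (high density or tillering, long
maturities) are penalised in dry finishes while conservative designs (skip
rows, low density, early maturity) are not — the classic dryland trade-off.
Biomass is transpiration-efficiency times effective water use, saturating
smoothly towards a Michaelis-type nitrogen-supply ceiling
(biomass = c (1 - exp(-TE.W/c)), so yields remain continuous across
years); yield = harvest_index x biomass, bounded by a potential. A crop with yield below the failure threshold is flagged failed
(this drives the failed/harvested cost split in the economics layer).

The model is deterministic: identical weather and parameters give identical
yields. It aims for the right *behaviours* (monotone in water supply,
saturating in N, responsive to every factorial axis), not for the yield
magnitudes of any particular station.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import DailyWeatherSeries
from .errors import CoverageError, InputError, ParameterError

__all__ = [
    "SoilProfile",
    "CropDesign",
    "Environment",
    "YieldRecord",
    "CropProxyParams",
    "SOIL_PRESETS",
    "simulate_crop",
    "simulate_factorial",
    "simulate_yield_grid",
    "thermal_time",
    "month_label",
    "month_number",
]

MONTH_LABELS = {m: calendar.month_abbr[m] for m in range(1, 13)}
LABEL_MONTHS = {v: k for k, v in MONTH_LABELS.items()}

MATURITIES = ("early", "medium", "late")
TILLERING = ("none", "medium", "high")
ROW_CONFIGS = ("solid", "single_skip")


def month_label(m: int) -> str:
    return MONTH_LABELS[m]


def month_number(w) -> int:
    return int(w) if not isinstance(w, str) else LABEL_MONTHS[w.capitalize()[:3]]


@dataclass(frozen=True)
class SoilProfile:
    """One site-soil: plant-available water capacity and surface properties."""

    label: str
    pawc: float  # mm
    runoff_curve: float = 0.25  # fraction of rain above the threshold lost
    evap_coeff: float = 3.0  # mm/day at a full profile

    def __post_init__(self):
        if self.pawc <= 0:
            raise ParameterError("PAWC must be > 0")


# PAWC presets (mm) as printed for the four stations; the PAW column is
# internally inconsistent with PAWC for some soils and is not used.
SOIL_PRESETS: dict[str, dict[str, float]] = {
    "Capella": {"high": 415.0, "medium": 274.0, "low": 146.0},
    "Dalby": {"high": 400.0, "medium": 344.0, "low": 274.0},
    "Goondiwindi": {"high": 313.0, "medium": 361.0, "low": 310.0},
    "Moree": {"high": 254.0, "medium": 304.0, "low": 124.0},
}


@dataclass(frozen=True)
class CropDesign:
    """One G x M combination: genetics (maturity, tillering) and management
    (plant density, row configuration, nitrogen rate)."""

    maturity: str = "medium"  # early | medium | late
    tillering: str = "medium"  # none | medium | high
    density: float = 5.0  # plants m^-2
    row_config: str = "solid"  # solid | single_skip
    n_rate: float = 50.0  # kg N ha^-1

    def __post_init__(self):
        if self.maturity not in MATURITIES:
            raise ParameterError(f"maturity must be one of {MATURITIES}")
        if self.tillering not in TILLERING:
            raise ParameterError(f"tillering must be one of {TILLERING}")
        if self.row_config not in ROW_CONFIGS:
            raise ParameterError(f"row_config must be one of {ROW_CONFIGS}")

    @property
    def design_id(self) -> str:
        return (
            f"{self.maturity}/{self.tillering}/d{self.density:g}/"
            f"{self.row_config}/N{self.n_rate:g}"
        )


@dataclass(frozen=True)
class Environment:
    """The E context of one simulation: site, soil, starting water, window."""

    site_id: str
    soil: SoilProfile
    isw_frac: float  # fraction of PAWC full at sowing
    sowing_window: str  # month label, Sep..Jan

    def __post_init__(self):
        if not 0.0 < self.isw_frac <= 1.0:
            raise ParameterError("isw_frac must be in (0, 1]")

    @property
    def sowing_month(self) -> int:
        return month_number(self.sowing_window)


@dataclass
class YieldRecord:
    environment: Environment
    design: CropDesign
    year: int
    trace_id: int
    yield_t_ha: float
    failed: bool


@dataclass
class CropProxyParams:
    """All tunable crop-proxy constants, with units.

    Declared once here; none of them is fitted to any published yield.
    """

    base_temp: float = 11.0  # deg C, thermal-time base
    tt_targets: dict = field(
        default_factory=lambda: {"early": 1500.0, "medium": 1700.0, "late": 1900.0}
    )  # deg C d sowing->maturity
    transpiration_efficiency: float = 0.028  # t biomass ha^-1 per mm transpired
    harvest_index: float = 0.45
    kl: float = 0.08  # fraction of the bucket extractable per day
    demand_coeff: float = 0.32  # mm demand per MJ m^-2 radiation
    runoff_thresh: float = 25.0  # mm/day before runoff starts
    biomass_max: float = 20.0  # t/ha, asymptote of the N ceiling
    n_half_sat: float = 40.0  # kg N ha^-1, Michaelis constant
    skip_row_factor: float = 0.8  # demand multiplier for single skip
    anthesis_frac: float = 0.55  # fraction of tt_target at anthesis
    post_water_frac: float = 0.35  # grain fill needs this share of water use
    tillering_mult: dict = field(
        default_factory=lambda: {"none": 0.85, "medium": 1.0, "high": 1.15}
    )
    density_intercept: float = 0.55  # demand factor = intercept + slope*density
    density_slope: float = 0.09
    potential_yield: float = 12.0  # t/ha hard bound
    failure_threshold: float = 0.2  # t/ha below which the crop is 'failed'
    horizon_days: int = 180  # fixed simulated season length

    def demand_factor(self, design: CropDesign) -> float:
        f = self.density_intercept + self.density_slope * design.density
        f *= self.tillering_mult[design.tillering]
        if design.row_config == "single_skip":
            f *= self.skip_row_factor
        return f

    def n_ceiling(self, n_rate: float) -> float:
        """Michaelis-type biomass ceiling (t/ha) from the N rate."""
        return self.biomass_max * n_rate / (n_rate + self.n_half_sat)


def thermal_time(maxt, mint, base_temp: float = 11.0) -> np.ndarray:
    """Daily thermal time (deg C d) above the base temperature."""
    tmean = (np.asarray(maxt, float) + np.asarray(mint, float)) / 2.0
    return np.maximum(0.0, tmean - base_temp)


# ---------------------------------------------------------------------------
# Vectorized bucket kernel
# ---------------------------------------------------------------------------


def simulate_yield_grid(
    rain: np.ndarray,  # (n_ty, n_days)
    cum_tt: np.ndarray,  # (n_ty, n_days) cumulative thermal time
    radn: np.ndarray,  # (n_ty, n_days)
    case: Mapping[str, np.ndarray],  # per-combo arrays, each (n_combo,)
    params: CropProxyParams,
    return_balance: bool = False,
):
    """Yields (t/ha) for every (combo, trace-year) pair.

    ``case`` needs: pawc, sw0, runoff_curve, evap_coeff, demand_f,
    tt_target, n_cap. The daily loop runs over the fixed horizon; water
    uptake stops once cumulative thermal time passes the maturity target.
    """
    n_ty, n_days = rain.shape
    pawc = np.asarray(case["pawc"], float)[:, None]
    sw = np.asarray(case["sw0"], float)[:, None] * np.ones((1, n_ty))
    rc = np.asarray(case["runoff_curve"], float)[:, None]
    ec = np.asarray(case["evap_coeff"], float)[:, None]
    df_ = np.asarray(case["demand_f"], float)[:, None]
    ttt = np.asarray(case["tt_target"], float)[:, None]
    n_cap = np.asarray(case["n_cap"], float)[:, None]

    transp_cum = np.zeros_like(sw)
    transp_post = np.zeros_like(sw)  # water use during grain fill
    loss_cum = np.zeros_like(sw)  # runoff + drainage
    evap_cum = np.zeros_like(sw)
    anthesis_tt = params.anthesis_frac * ttt
    for d in range(n_days):
        r = rain[:, d][None, :]
        runoff = rc * np.maximum(r - params.runoff_thresh, 0.0)
        sw = sw + (r - runoff)
        drain = np.maximum(sw - pawc, 0.0)
        sw = sw - drain
        evap = ec * sw / pawc
        sw = sw - evap
        tt_d = cum_tt[:, d][None, :]
        active = tt_d < ttt
        demand = params.demand_coeff * radn[:, d][None, :] * df_ * active
        transp = np.minimum(demand, params.kl * sw)
        sw = sw - transp
        transp_cum += transp
        transp_post += transp * (tt_d >= anthesis_tt)
        evap_cum += evap
        loss_cum += runoff + drain

    # grain fill needs its share of the season's water: designs that exhaust
    # the bucket before anthesis are penalised in dry finishes
    effective_water = np.minimum(
        transp_cum, transp_post / params.post_water_frac
    )
    # smooth saturating N ceiling: biomass -> n_cap as water use grows, with
    # no atom at the cap (yields stay continuous across years)
    potential = params.transpiration_efficiency * effective_water
    biomass = n_cap * -np.expm1(-potential / n_cap)
    yields = np.minimum(params.harvest_index * biomass, params.potential_yield)
    if return_balance:
        balance = {
            "transpiration": transp_cum,
            "soil_evap": evap_cum,
            "runoff": loss_cum,
            "sw_final": sw,
        }
        return yields, balance
    return yields


def _case_arrays(
    pairs: Sequence[tuple[Environment, CropDesign]], params: CropProxyParams
) -> dict[str, np.ndarray]:
    return {
        "pawc": np.array([e.soil.pawc for e, _ in pairs]),
        "sw0": np.array([e.isw_frac * e.soil.pawc for e, _ in pairs]),
        "runoff_curve": np.array([e.soil.runoff_curve for e, _ in pairs]),
        "evap_coeff": np.array([e.soil.evap_coeff for e, _ in pairs]),
        "demand_f": np.array([params.demand_factor(d) for _, d in pairs]),
        "tt_target": np.array([params.tt_targets[d.maturity] for _, d in pairs]),
        "n_cap": np.array([params.n_ceiling(d.n_rate) for _, d in pairs]),
    }


def _season_arrays(
    weather: DailyWeatherSeries, sowing_date: pd.Timestamp, params: CropProxyParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    end = sowing_date + pd.Timedelta(days=params.horizon_days)
    sl = weather.slice(sowing_date, end)
    rain = sl["rain"].to_numpy()
    tt = np.cumsum(thermal_time(sl["maxt"], sl["mint"], params.base_temp))
    radn = sl["radn"].to_numpy()
    return rain, tt, radn


def simulate_crop(
    weather: DailyWeatherSeries,
    env: Environment,
    design: CropDesign,
    params: CropProxyParams | None = None,
    year: int | None = None,
    trace_id: int = 0,
    seed: int | None = None,  # accepted for interface symmetry; model is deterministic
    return_balance: bool = False,
):
    """One crop: sown on the 1st of the environment's window month.

    ``year`` defaults to the first year for which the weather series covers
    the full season. Raises :class:`CoverageError` on a coverage gap.
    """
    params = params or CropProxyParams()
    if year is None:
        year = weather.start.year
        if pd.Timestamp(year=year, month=env.sowing_month, day=1) < weather.start:
            year += 1
    sowing = pd.Timestamp(year=year, month=env.sowing_month, day=1)
    rain, tt, radn = _season_arrays(weather, sowing, params)
    case = _case_arrays([(env, design)], params)
    out = simulate_yield_grid(
        rain[None, :], tt[None, :], radn[None, :], case, params,
        return_balance=return_balance,
    )
    yields, balance = out if return_balance else (out, None)
    y = float(yields[0, 0])
    rec = YieldRecord(
        environment=env,
        design=design,
        year=year,
        trace_id=trace_id,
        yield_t_ha=y,
        failed=y < params.failure_threshold,
    )
    if return_balance:
        return rec, {k: float(v[0, 0]) for k, v in balance.items()}
    return rec


def simulate_factorial(
    weather_traces: Mapping[int, DailyWeatherSeries],
    envs: Sequence[Environment],
    designs: Sequence[CropDesign],
    years: Sequence[int],
    params: CropProxyParams | None = None,
) -> pd.DataFrame:
    """Tidy yield table over every (env, design, year, trace) combination.

    ``weather_traces`` maps trace id (0 = observed) to a full multi-year
    daily series. Count of rows = |envs| x |designs| x |years| x |traces|.
    Output columns: site, soil, isw, window, maturity, tillering, density,
    row_config, n_rate, year, trace, yield, failed.
    """
    params = params or CropProxyParams()
    if not envs or not designs or not list(years):
        raise InputError("envs, designs and years must be non-empty")
    trace_ids = sorted(weather_traces)
    frames = []
    for month in sorted({e.sowing_month for e in envs}):
        month_envs = [e for e in envs if e.sowing_month == month]
        pairs = [(e, d) for e in month_envs for d in designs]
        case = _case_arrays(pairs, params)
        ty_rain, ty_tt, ty_radn, ty_meta = [], [], [], []
        for year in years:
            sowing = pd.Timestamp(year=int(year), month=month, day=1)
            for tid in trace_ids:
                r, t, s = _season_arrays(weather_traces[tid], sowing, params)
                ty_rain.append(r)
                ty_tt.append(t)
                ty_radn.append(s)
                ty_meta.append((int(year), tid))
        n_days = min(len(r) for r in ty_rain)
        rain = np.stack([r[:n_days] for r in ty_rain])
        tt = np.stack([t[:n_days] for t in ty_tt])
        radn = np.stack([s[:n_days] for s in ty_radn])
        yields = simulate_yield_grid(rain, tt, radn, case, params)
        years_arr = np.array([m[0] for m in ty_meta])
        traces_arr = np.array([m[1] for m in ty_meta])
        n_combo, n_ty = yields.shape
        frames.append(
            pd.DataFrame(
                {
                    "site": np.repeat([e.site_id for e, _ in pairs], n_ty),
                    "soil": np.repeat([e.soil.label for e, _ in pairs], n_ty),
                    "isw": np.repeat([e.isw_frac for e, _ in pairs], n_ty),
                    "window": np.repeat([e.sowing_window for e, _ in pairs], n_ty),
                    "maturity": np.repeat([d.maturity for _, d in pairs], n_ty),
                    "tillering": np.repeat([d.tillering for _, d in pairs], n_ty),
                    "density": np.repeat([d.density for _, d in pairs], n_ty),
                    "row_config": np.repeat([d.row_config for _, d in pairs], n_ty),
                    "n_rate": np.repeat([d.n_rate for _, d in pairs], n_ty),
                    "year": np.tile(years_arr, n_combo),
                    "trace": np.tile(traces_arr, n_combo),
                    "yield": yields.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["failed"] = out["yield"] < params.failure_threshold
    sort_cols = [
        "site", "soil", "isw", "window", "maturity", "tillering",
        "density", "row_config", "n_rate", "year", "trace",
    ]
    return out.sort_values(sort_cols, kind="stable").reset_index(drop=True)
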