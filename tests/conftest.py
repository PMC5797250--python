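import numpy as np
import pandas as pd
import pytest

from cropskill import ClimateGenParams, generate_daily_weather, generate_enso_index
from cropskill.climate import DailyWeatherSeries


@pytest.fixture(scope="session")
def params36():
    return ClimateGenParams(site_id="Dalby", seed=5)


@pytest.fixture(scope="session")
def obs36(params36):
    """36 calendar years of synthetic station weather (hindcast + spill)."""
    return generate_daily_weather(params36, 36)


@pytest.fixture(scope="session")
def long_climate():
    """500-year teleconnected world for Monte Carlo checks (pre-ns-epoch
    start year keeps pandas datetimes in range)."""
    enso = generate_enso_index(0.8, 501, seed=42, start_year=1700)
    p = ClimateGenParams(teleconnection_strength=0.6, seed=7, start_year=1700)
    return p, enso, generate_daily_weather(p, 501, enso)


def make_weather_from_annual_totals(totals_by_year, month=10, site_id="toy"):
    """A gap-free daily series whose (month, 3)-window totals are exactly the
    given per-year values: all window rain falls on the window's 15th day."""
    years = sorted(totals_by_year)
    start = pd.Timestamp(year=years[0], month=1, day=1)
    end = pd.Timestamp(year=years[-1] + 1, month=12, day=31)
    idx = pd.date_range(start, end, freq="D")
    data = pd.DataFrame(
        {
            "rain": 0.0,
            "maxt": 30.0,
            "mint": 15.0,
            "radn": 22.0,
        },
        index=idx,
    )
    for y, tot in totals_by_year.items():
        data.loc[pd.Timestamp(year=y, month=month, day=15), "rain"] = float(tot)
    return DailyWeatherSeries(site_id=site_id, data=data).validate()
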