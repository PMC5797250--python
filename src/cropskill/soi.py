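"""SOI-phase statistical forecasting: 5-phase classification of consecutive
monthly index values and cross-validated analogue-year forecast
distributions.

Each (prev, curr) pair of monthly index values is assigned to the nearest of
five phase centroids in the plane: consistently negative, consistently
positive, rapidly falling, rapidly rising and near zero. An analogue
forecast for a 3-month window collects the observed window totals of all
years sharing the issue month's phase (leave-one-out: the forecast year is
always excluded) and converts them to category probabilities against the
climatological median and terciles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import (
    ClimatologySummary,
    DailyWeatherSeries,
    EnsoIndexSeries,
    WindowStats,
    window_totals,
)
from .errors import ClassificationError, InsufficientAnaloguesError

__all__ = [
    "PHASE_LABELS",
    "DEFAULT_CENTROIDS",
    "AnalogueForecast",
    "classify_phase",
    "phase_table",
    "analogue_forecast",
    "analogue_forecast_or_climatology",
]

# Fixed label order; also the deterministic tie-break order.
PHASE_LABELS = (
    "consistently_negative",
    "consistently_positive",
    "rapidly_falling",
    "rapidly_rising",
    "near_zero",
)

# Centroids in the (prev, curr) plane on the sd-10 index scale. The original
# cluster geometry is not published; these reproduce the five named
# behaviours and are fully configurable.
DEFAULT_CENTROIDS: dict[str, tuple[float, float]] = {
    "consistently_negative": (-10.0, -10.0),
    "consistently_positive": (10.0, 10.0),
    "rapidly_falling": (8.0, -8.0),
    "rapidly_rising": (-8.0, 8.0),
    "near_zero": (0.0, 0.0),
}


@dataclass
class AnalogueForecast:
    """Analogue-year forecast distribution for one issue.

    ``distribution`` holds the analogue years' observed window totals (mm);
    ``category_probs`` has keys above_median, below_median, tercile_1,
    tercile_2, tercile_3. ``fallback`` flags a climatology substitution
    made because the analogue set was empty."""

    site_id: str
    issue_month: int
    target_year: int
    window_months: int
    phase: str
    analogue_years: list[int]
    distribution: pd.Series
    category_probs: dict[str, float]
    fallback: bool = False


def classify_phase(
    index_prev: float,
    index_curr: float,
    centroids: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Nearest-centroid phase of a consecutive monthly index pair.

    Euclidean distance in the (prev, curr) plane; ties resolve in the fixed
    ``PHASE_LABELS`` order.
    """
    if not (np.isfinite(index_prev) and np.isfinite(index_curr)):
        raise ClassificationError("both index values must be finite")
    centroids = centroids or DEFAULT_CENTROIDS
    best_label, best_d2 = None, np.inf
    for label in PHASE_LABELS:
        cp, cc = centroids[label]
        d2 = (index_prev - cp) ** 2 + (index_curr - cc) ** 2
        if d2 < best_d2 - 1e-12:
            best_label, best_d2 = label, d2
    return best_label


def phase_table(
    enso: EnsoIndexSeries,
    centroids: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Phase of every month with a defined (prev, curr) pair.

    Columns: year, month, index_prev, index_curr, phase. The first month of
    the series has no predecessor and is omitted.
    """
    vals = enso.values
    rows = []
    for i in range(1, len(vals)):
        per = vals.index[i]
        rows.append(
            {
                "year": per.year,
                "month": per.month,
                "index_prev": float(vals.iloc[i - 1]),
                "index_curr": float(vals.iloc[i]),
            }
        )
    df = pd.DataFrame(rows)
    df["phase"] = [
        classify_phase(p, c, centroids)
        for p, c in zip(df["index_prev"], df["index_curr"])
    ]
    return df


def _category_probs(distribution: np.ndarray, stats: WindowStats) -> dict[str, float]:
    """Fractions of analogue totals in each climatological category.

    Ties at a boundary fall to the lower category, matching the event
    definitions used in verification.
    """
    d = np.asarray(distribution, dtype=float)
    p_above = float(np.mean(d > stats.median))
    p_t1 = float(np.mean(d <= stats.t1_upper))
    p_t3 = float(np.mean(d > stats.t2_upper))
    return {
        "above_median": p_above,
        "below_median": 1.0 - p_above,
        "tercile_1": p_t1,
        "tercile_2": 1.0 - p_t1 - p_t3,
        "tercile_3": p_t3,
    }


def analogue_forecast(
    obs: DailyWeatherSeries,
    enso: EnsoIndexSeries,
    issue_month: int,
    target_year: int,
    climatology: ClimatologySummary,
    window_months: int = 3,
    reference_years: list[int] | None = None,
    centroids: dict[str, tuple[float, float]] | None = None,
    phases: pd.DataFrame | None = None,
    totals: pd.Series | None = None,
) -> AnalogueForecast:
    """Cross-validated analogue-year forecast for one issue.

    The analogue set is every year in the reference period whose issue-month
    phase matches the target year's phase, minus the target year itself.
    ``phases`` and ``totals`` may pass precomputed tables for batch runs.

    Raises :class:`InsufficientAnaloguesError` when fewer than two analogue
    years remain; callers may fall back to climatology (see
    :func:`analogue_forecast_or_climatology`).
    """
    if phases is None:
        phases = phase_table(enso, centroids)
    if totals is None:
        totals = window_totals(obs, issue_month, window_months)
    month_phases = phases[phases["month"] == issue_month].set_index("year")["phase"]
    try:
        target_phase = month_phases[target_year]
    except KeyError as exc:
        raise ClassificationError(
            f"no phase for issue {target_year}-{issue_month:02d}"
        ) from exc
    candidates = month_phases.index[month_phases == target_phase]
    years = [
        int(y)
        for y in candidates
        if y != target_year
        and y in totals.index
        and (reference_years is None or y in reference_years)
    ]
    if len(years) < 2:
        raise InsufficientAnaloguesError(
            f"{len(years)} analogue years for phase '{target_phase}' at issue "
            f"{target_year}-{issue_month:02d}; >= 2 required"
        )
    dist = totals[years]
    stats = climatology.window(issue_month, window_months)
    return AnalogueForecast(
        site_id=obs.site_id,
        issue_month=issue_month,
        target_year=target_year,
        window_months=window_months,
        phase=target_phase,
        analogue_years=years,
        distribution=dist,
        category_probs=_category_probs(dist.to_numpy(), stats),
    )


def analogue_forecast_or_climatology(
    obs: DailyWeatherSeries,
    enso: EnsoIndexSeries,
    issue_month: int,
    target_year: int,
    climatology: ClimatologySummary,
    **kwargs,
) -> AnalogueForecast:
    """As :func:`analogue_forecast`, but substituting the climatological
    (leave-one-out) distribution when the analogue set is empty or the
    issue month's phase is undefined (no preceding index value); the
    substitution is flagged via ``fallback=True``."""
    try:
        return analogue_forecast(
            obs, enso, issue_month, target_year, climatology, **kwargs
        )
    except (InsufficientAnaloguesError, ClassificationError):
        window_months = kwargs.get("window_months", 3)
        totals = kwargs.get("totals")
        if totals is None:
            totals = window_totals(obs, issue_month, window_months)
        dist = totals[totals.index != target_year]
        stats = climatology.window(issue_month, window_months)
        return AnalogueForecast(
            site_id=obs.site_id,
            issue_month=issue_month,
            target_year=target_year,
            window_months=window_months,
            phase="unclassified",
            analogue_years=[int(y) for y in dist.index],
            distribution=dist,
            category_probs=_category_probs(dist.to_numpy(), stats),
            fallback=True,
        )
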