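"""Probabilistic forecast verification for rainfall and simulated-yield
events.

Implements the standard Murphy-style scores used to compare a probabilistic
forecast system with climatology: the Brier score and Brier skill score
(BSS = 1 - BS/BS_ref), percent consistent (how often the favoured category
verified), reliability diagrams with a count-weighted regression slope and
RMSE, running-window skill series, and the shift/dispersion pair AMD
(absolute mean deviation of the forecast mean from climatology) and VR
(forecast variance over climatological variance).

Event conventions, fixed for reproducible outcomes: *above median* is a
strict exceedance (a value exactly at the median counts as below);
*tercile 1* is value <= t1_upper; *tercile 3* is value > t2_upper — ties at
a boundary always fall to the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .climate import WindowStats, summarize_window_totals
from .errors import InputError, UndefinedMetricError

__all__ = [
    "EventDefinition",
    "ReliabilitySummary",
    "VerificationResult",
    "event_outcomes",
    "forecast_probability",
    "brier_skill_score",
    "percent_consistent",
    "running_skill",
    "reliability_curve",
    "shift_dispersion",
    "yield_event_skill",
    "bss_standard_error",
]

EVENT_KINDS = ("above_median", "tercile_1", "tercile_3")


@dataclass(frozen=True)
class EventDefinition:
    """A binary rainfall/yield event against a climatological reference."""

    kind: str  # above_median | tercile_1 | tercile_3
    median: float
    t1_upper: float
    t2_upper: float

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise InputError(f"unknown event kind '{self.kind}'")

    @property
    def base_rate(self) -> float:
        return 0.5 if self.kind == "above_median" else 1.0 / 3.0

    @classmethod
    def from_window_stats(cls, kind: str, stats: WindowStats) -> "EventDefinition":
        return cls(
            kind=kind,
            median=stats.median,
            t1_upper=stats.t1_upper,
            t2_upper=stats.t2_upper,
        )

    def occurs(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "above_median":
            return (v > self.median).astype(int)
        if self.kind == "tercile_1":
            return (v <= self.t1_upper).astype(int)
        return (v > self.t2_upper).astype(int)


@dataclass
class ReliabilitySummary:
    """Binned reliability table with its count-weighted regression."""

    bins: pd.DataFrame  # bin_center, mean_prob, obs_freq, count (non-empty only)
    slope_b: float
    rmse: float
    sharpness_histogram: np.ndarray  # counts per bin, all bins
    n_forecasts: int


@dataclass
class VerificationResult:
    """Scores for one event definition over a set of forecast issues."""

    event: EventDefinition
    n_forecasts: int
    BS: float
    BS_ref: float
    BSS: float
    percent_consistent: float
    AMD: float | None = None
    VR: float | None = None
    reliability: ReliabilitySummary | None = None


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def event_outcomes(values, event: EventDefinition) -> np.ndarray:
    """Binary outcome series (1 = event occurred) for per-year values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("empty value series")
    return event.occurs(v)


def forecast_probability(distribution, event: EventDefinition) -> float:
    """Fraction of forecast-distribution members satisfying the event."""
    d = np.asarray(distribution, dtype=float)
    if d.size < 2:
        raise InputError("forecast distribution needs >= 2 members")
    return float(event.occurs(d).mean())


def _check_pairs(probs, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise InputError("probs and outcomes must be equal-length 1-d series")
    if ((p < 0) | (p > 1)).any():
        raise InputError("probabilities must lie in [0, 1]")
    if not np.isin(o, (0.0, 1.0)).all():
        raise InputError("outcomes must be 0/1")
    return p, o


def brier_skill_score(probs, outcomes, base_rate: float) -> tuple[float, float, float]:
    """(BS, BS_ref, BSS) with BS = mean (p - o)^2 and the climatological
    reference forecast issuing ``base_rate`` every time."""
    p, o = _check_pairs(probs, outcomes)
    bs = float(np.mean((p - o) ** 2))
    bs_ref = float(np.mean((base_rate - o) ** 2))
    if bs_ref == 0.0:
        raise UndefinedMetricError("degenerate outcomes: reference Brier score is 0")
    return bs, bs_ref, 1.0 - bs / bs_ref


def bss_standard_error(probs, outcomes, base_rate: float) -> float:
    """Delta-method Monte Carlo standard error of the BSS over issues.

    With a = (p-o)^2 and b = (base-o)^2 per issue, BSS = 1 - mean(a)/mean(b);
    the SE propagates the sampling covariance of the two means.
    """
    p, o = _check_pairs(probs, outcomes)
    a = (p - o) ** 2
    b = (base_rate - o) ** 2
    n = len(a)
    am, bm = a.mean(), b.mean()
    if bm == 0.0 or n < 2:
        raise UndefinedMetricError("SE undefined")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    cab = np.cov(a, b, ddof=1)[0, 1]
    var = (va / bm**2 - 2 * am * cab / bm**3 + am**2 * vb / bm**4) / n
    return float(np.sqrt(max(var, 0.0)))


def percent_consistent(probs, outcomes, base_rate: float) -> float:
    """Share (%) of forecasts whose favoured category verified.

    A forecast favours the event iff p > base_rate, the complement iff
    p < base_rate; forecasts issued exactly at the base rate are excluded
    from the denominator. Undefined (raises) when every forecast sits at
    the base rate.
    """
    p, o = _check_pairs(probs, outcomes)
    considered = p != base_rate
    if not considered.any():
        raise UndefinedMetricError("all forecasts at the base rate")
    consistent = ((p > base_rate) & (o == 1)) | ((p < base_rate) & (o == 0))
    return 100.0 * float(consistent[considered].sum()) / float(considered.sum())


def running_skill(
    probs,
    outcomes,
    years,
    window_years: int = 30,
    metric: str | Callable = "bss",
    base_rate: float = 0.5,
) -> pd.Series:
    """Metric evaluated on each contiguous ``window_years``-year window,
    indexed by the window's end year. ``years`` may repeat (pooled sites)."""
    p, o = _check_pairs(probs, outcomes)
    y = np.asarray(years, dtype=int)
    if y.shape != p.shape:
        raise InputError("years must align with probs/outcomes")
    y0, y1 = int(y.min()), int(y.max())
    span = y1 - y0 + 1
    if span < window_years:
        raise InputError(f"span {span} shorter than window {window_years}")
    if callable(metric):
        fn = metric
    elif metric == "bss":
        fn = lambda pp, oo: brier_skill_score(pp, oo, base_rate)[2]
    elif metric == "percent_consistent":
        fn = lambda pp, oo: percent_consistent(pp, oo, base_rate)
    else:
        raise InputError(f"unknown metric '{metric}'")
    out = {}
    for end in range(y0 + window_years - 1, y1 + 1):
        mask = (y >= end - window_years + 1) & (y <= end)
        out[end] = fn(p[mask], o[mask])
    return pd.Series(out, dtype=float)


def reliability_curve(probs, outcomes, n_bins: int = 10) -> ReliabilitySummary:
    """Reliability diagram over equal-width probability bins on [0, 1].

    The slope ``b`` comes from a least-squares line of observed frequency on
    mean forecast probability, weighted by bin counts; ``rmse`` is the
    count-weighted root mean square residual of that regression. Empty bins
    are omitted from the table (the sharpness histogram keeps all bins).
    """
    p, o = _check_pairs(probs, outcomes)
    if len(p) < n_bins:
        raise InputError("need at least n_bins forecasts")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    rows = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        sel = idx == b
        rows.append(
            {
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "mean_prob": float(p[sel].mean()),
                "obs_freq": float(o[sel].mean()),
                "count": int(counts[b]),
            }
        )
    bins = pd.DataFrame(rows)
    if len(bins) < 2:
        raise UndefinedMetricError("fewer than 2 non-empty bins: slope undefined")
    w = bins["count"].to_numpy(dtype=float)
    x = bins["mean_prob"].to_numpy()
    yv = bins["obs_freq"].to_numpy()
    slope, intercept = np.polyfit(x, yv, 1, w=np.sqrt(w))
    resid = yv - (slope * x + intercept)
    rmse = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
    return ReliabilitySummary(
        bins=bins,
        slope_b=float(slope),
        rmse=rmse,
        sharpness_histogram=counts,
        n_forecasts=len(p),
    )


def shift_dispersion(forecast_totals, climatology_totals) -> tuple[float, float]:
    """(AMD, VR) of a forecast distribution against climatology.

    AMD = |mean(forecast) - mean(climatology)| (shift, mm);
    VR = sample variance(forecast) / sample variance(climatology)
    (dispersion; < 1 means a sharper-than-climatology forecast).
    """
    f = np.asarray(forecast_totals, dtype=float)
    c = np.asarray(climatology_totals, dtype=float)
    if f.size < 2 or c.size < 2:
        raise InputError("both samples need >= 2 members")
    var_c = c.var(ddof=1)
    if var_c == 0.0:
        raise UndefinedMetricError("zero climatological variance: VR undefined")
    return float(abs(f.mean() - c.mean())), float(f.var(ddof=1) / var_c)


# ---------------------------------------------------------------------------
# Yield-event skill over a factorial yield table
# ---------------------------------------------------------------------------

DESIGN_COLS = ["maturity", "tillering", "density", "row_config", "n_rate"]
ENV_COLS = ["site", "soil", "isw", "window"]


def yield_event_skill(
    records: pd.DataFrame,
    kinds: Sequence[str] = EVENT_KINDS,
    group_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per (environment, design, event) forecast skill for simulated yields.

    ``records`` is the tidy factorial yield table (columns as exported by
    the crop module: site, soil, isw, window, design factors, year, trace,
    yield). Trace 0 is the observed-weather run and defines both the yield
    climatology (in-sample across years) and the outcomes; traces >= 1 are
    ensemble members and give the forecast probability per year. Returns a
    tidy frame with one row per group x event kind.
    """
    if group_cols is None:
        group_cols = [c for c in ENV_COLS + DESIGN_COLS if c in records.columns]
    required = {"year", "trace", "yield"}
    if not required.issubset(records.columns):
        raise InputError(f"records must have columns {sorted(required)}")
    rows = []
    for key, grp in records.groupby(list(group_cols), sort=True, observed=True):
        obs = grp[grp["trace"] == 0].set_index("year")["yield"].sort_index()
        ens = grp[grp["trace"] > 0]
        if obs.empty or ens.empty:
            raise InputError(f"group {key}: observed trace or members missing")
        stats = summarize_window_totals(obs)
        member_by_year = {
            y: sub["yield"].to_numpy() for y, sub in ens.groupby("year")
        }
        if set(member_by_year) != set(obs.index):
            raise InputError(f"group {key}: member years do not match trace 0")
        years = obs.index.to_numpy()
        for kind in kinds:
            ev = EventDefinition.from_window_stats(kind, stats)
            outs = event_outcomes(obs.to_numpy(), ev)
            probs = np.array(
                [forecast_probability(member_by_year[y], ev) for y in years]
            )
            bs, bs_ref, bss = brier_skill_score(probs, outs, ev.base_rate)
            try:
                pc = percent_consistent(probs, outs, ev.base_rate)
            except UndefinedMetricError:
                pc = np.nan
            amds, vrs = zip(
                *(
                    shift_dispersion(member_by_year[y], obs.to_numpy())
                    for y in years
                )
            )
            rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            rec.update(
                event=kind,
                n=len(years),
                BS=bs,
                BS_ref=bs_ref,
                BSS=bss,
                percent_consistent=pc,
                AMD=float(np.mean(amds)),
                VR=float(np.mean(vrs)),
            )
            rows.append(rec)
    return pd.DataFrame(rows)
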