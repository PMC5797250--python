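"""Economics and decision layer: profit, downside risk, the BSS-filtered
forecast search, and the value of forecast-informed crop designs.

Four strategies are compared over the hindcast years for one site x soil:

* **farmer** — a fixed locally-typical design every year;
* **static_optimal** — the single design maximising mean profit over all
  years under observed weather;
* **forecast_optimal** — each year, among designs whose above/below-median
  yield forecasts beat climatology (BSS > 0), the design with the highest
  ensemble-mean profit; realised under observed weather;
* **perfect_knowledge** — each year the profit-maximising design under
  observed weather.

Value numbers (AU$ ha^-1, mean over years):

    Value_optS   = mean profit(static_optimal)   - mean profit(farmer)
    Value_optSCF = mean profit(forecast_optimal) - mean profit(static_optimal)
    Value_PK     = mean profit(perfect_knowledge) - mean profit(farmer)

Downside risk (DSR) is the percentage of years with profit strictly below
a threshold (default AU$600 ha^-1).

Profit decomposition: the published failed/harvested totals (161 / 211
AU$ ha^-1), the 1 %-of-gross insurance and the per-kg urea price cannot all
be fixed constants simultaneously; here 161/211 are fixed non-N,
non-insurance costs, with insurance and the *incremental* nitrogen cost
above a 50 kg N ha^-1 base added on top. This reproduces the failed-crop
profit of -161 exactly while keeping N rates economically distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crop import CropDesign
from .errors import InputError, OptimizationError, ParameterError

__all__ = [
    "EconParams",
    "StrategyProfile",
    "ValueReport",
    "profit",
    "downside_risk",
    "count_crop_year_simulations",
    "profit_matrix",
    "optimize_static",
    "static_profile",
    "perfect_knowledge",
    "select_forecast_designs",
    "value_report",
]


@dataclass
class EconParams:
    price: float = 254.0  # AU$ t^-1
    insurance_rate: float = 0.01  # fraction of gross income
    cost_failed: float = 161.0  # AU$ ha^-1 fixed cost, failed crop
    cost_harvested: float = 211.0  # AU$ ha^-1 fixed cost, harvested crop
    urea_price: float = 0.30  # AU$ kg^-1 urea
    urea_n_fraction: float = 0.46  # kg N per kg urea
    n_base: float = 50.0  # kg N ha^-1 assumed inside the fixed costs
    dsr_threshold: float = 600.0  # AU$ ha^-1 downside-risk threshold

    def __post_init__(self):
        vals = [
            self.price, self.insurance_rate, self.cost_failed,
            self.cost_harvested, self.urea_price, self.urea_n_fraction,
            self.dsr_threshold,
        ]
        if any(v < 0 for v in vals) or self.insurance_rate >= 1:
            raise ParameterError("economic parameters must be >= 0, insurance < 1")


def profit(yield_t_ha, failed, n_rate, econ: EconParams | None = None):
    """Annual profit (AU$ ha^-1); vectorised over numpy inputs.

    gross = yield x price; profit = gross - insurance - fixed cost
    (failed or harvested) - incremental urea cost for N above the base rate.
    """
    econ = econ or EconParams()
    y = np.asarray(yield_t_ha, dtype=float)
    if (y < 0).any():
        raise InputError("yield must be >= 0")
    failed = np.asarray(failed, dtype=bool)
    gross = y * econ.price
    fixed = np.where(failed, econ.cost_failed, econ.cost_harvested)
    n_cost = (
        econ.urea_price
        * (np.asarray(n_rate, dtype=float) - econ.n_base)
        / econ.urea_n_fraction
    )
    out = gross * (1.0 - econ.insurance_rate) - fixed - n_cost
    return float(out) if out.ndim == 0 else out


def downside_risk(profits, threshold: float = 600.0) -> float:
    """Percentage of years with profit strictly below the threshold."""
    p = np.asarray(profits, dtype=float)
    if p.size == 0:
        raise InputError("empty profit series")
    return 100.0 * float((p < threshold).mean())


def count_crop_year_simulations(config: Mapping[str, Sequence | int]) -> int:
    """Total crop-year simulation count of a factorial configuration.

    ``config`` maps factor names to their level lists plus integers
    ``n_years`` and ``n_traces``. The product of all level counts times
    years times traces.
    """
    n = 1
    for key, levels in config.items():
        if key in ("n_years", "n_traces"):
            if int(levels) < 1:
                raise InputError(f"{key} must be >= 1")
            n *= int(levels)
            continue
        if not list(levels):
            raise InputError(f"factor '{key}' has no levels")
        n *= len(list(levels))
    return n


# ---------------------------------------------------------------------------
# Strategy profiles
# ---------------------------------------------------------------------------


@dataclass
class StrategyProfile:
    """Per-year design choice and realised profit of one strategy."""

    strategy: str  # farmer | static_optimal | forecast_optimal | perfect_knowledge
    design_by_year: dict[int, str]  # year -> design_id
    profits: pd.Series  # year -> realised profit, AU$ ha^-1
    dsr_threshold: float = 600.0
    fallback: bool = False  # forecast strategy fell back to the static optimum

    @property
    def mean_profit(self) -> float:
        return float(self.profits.mean())

    @property
    def dsr(self) -> float:
        return downside_risk(self.profits.to_numpy(), self.dsr_threshold)


@dataclass
class ValueReport:
    """Per site x soil value of information summary."""

    site: str
    soil: str
    farmer: StrategyProfile
    static_optimal: StrategyProfile
    forecast_optimal: StrategyProfile
    perfect_knowledge: StrategyProfile
    value_optS: float = field(init=False)
    value_optSCF: float = field(init=False)
    value_PK: float = field(init=False)

    def __post_init__(self):
        years = set(self.farmer.profits.index)
        for prof in (self.static_optimal, self.forecast_optimal, self.perfect_knowledge):
            if set(prof.profits.index) != years:
                raise InputError("all strategy profiles must share the year set")
        self.value_optS = self.static_optimal.mean_profit - self.farmer.mean_profit
        self.value_optSCF = (
            self.forecast_optimal.mean_profit - self.static_optimal.mean_profit
        )
        self.value_PK = self.perfect_knowledge.mean_profit - self.farmer.mean_profit

    @property
    def dsr_delta_optS(self) -> float:
        return self.static_optimal.dsr - self.farmer.dsr

    @property
    def dsr_delta_optSCF(self) -> float:
        return self.forecast_optimal.dsr - self.static_optimal.dsr

    def as_row(self) -> dict:
        return {
            "site": self.site,
            "soil": self.soil,
            "profit_farmer": self.farmer.mean_profit,
            "profit_optimized": self.static_optimal.mean_profit,
            "profit_forecast": self.forecast_optimal.mean_profit,
            "profit_pk": self.perfect_knowledge.mean_profit,
            "value_optS": self.value_optS,
            "value_optSCF": self.value_optSCF,
            "value_PK": self.value_PK,
            "dsr_farmer": self.farmer.dsr,
            "dsr_optimized": self.static_optimal.dsr,
            "dsr_delta": self.dsr_delta_optS,
        }


# ---------------------------------------------------------------------------
# Profit matrices and strategy optimisation
# ---------------------------------------------------------------------------


def profit_matrix(
    records: pd.DataFrame,
    designs: Sequence[CropDesign],
    econ: EconParams | None = None,
    trace: int | None = 0,
    failure_threshold: float = 0.2,
) -> pd.DataFrame:
    """Design x year profit matrix from a tidy yield table.

    ``trace=0`` gives observed-weather profits; ``trace=None`` averages the
    profit over all member traces (> 0) per (design, year) — the
    ensemble-expected profit used by the forecast strategy.
    """
    econ = econ or EconParams()
    df = records.copy()
    if trace is not None:
        df = df[df["trace"] == trace]
    else:
        df = df[df["trace"] > 0]
    if "failed" not in df.columns:
        df["failed"] = df["yield"] < failure_threshold
    df = df.assign(
        profit=profit(
            df["yield"].to_numpy(), df["failed"].to_numpy(),
            df["n_rate"].to_numpy(), econ,
        )
    )
    rows = {}
    for d in designs:
        sel = df[
            (df["maturity"] == d.maturity)
            & (df["tillering"] == d.tillering)
            & (df["density"] == d.density)
            & (df["row_config"] == d.row_config)
            & (df["n_rate"] == d.n_rate)
        ]
        if sel.empty:
            raise InputError(f"no records for design {d.design_id}")
        rows[d.design_id] = sel.groupby("year")["profit"].mean()
    mat = pd.DataFrame(rows).T
    if mat.isna().any().any():
        raise InputError("every design needs profits for every year")
    return mat


def _tie_break_order(designs: Sequence[CropDesign]) -> list[int]:
    """Candidate order for argmax ties: lower n_rate, then lower density,
    then listed order."""
    return sorted(
        range(len(designs)),
        key=lambda i: (designs[i].n_rate, designs[i].density, i),
    )


def _argmax_with_ties(values: np.ndarray, order: list[int], tol: float = 1e-9) -> int:
    best = values.max()
    for i in order:
        if values[i] >= best - tol:
            return i
    return int(np.argmax(values))


def optimize_static(
    profits: pd.DataFrame, designs: Sequence[CropDesign], econ: EconParams | None = None
) -> StrategyProfile:
    """The single design maximising mean profit across years (exhaustive
    search over ``designs``; rows of ``profits`` are observed-weather
    profits per design, columns years)."""
    econ = econ or EconParams()
    if profits.empty or not designs:
        raise OptimizationError("empty candidate set")
    means = profits.mean(axis=1).to_numpy()
    order = _tie_break_order(designs)
    best = _argmax_with_ties(means, order)
    did = designs[best].design_id
    series = profits.loc[did]
    return StrategyProfile(
        strategy="static_optimal",
        design_by_year={int(y): did for y in series.index},
        profits=series.astype(float),
        dsr_threshold=econ.dsr_threshold,
    )


def static_profile(
    profits: pd.DataFrame,
    design: CropDesign,
    econ: EconParams | None = None,
    strategy: str = "farmer",
) -> StrategyProfile:
    """Profile of a fixed design (e.g. the farmer baseline)."""
    econ = econ or EconParams()
    if design.design_id not in profits.index:
        raise OptimizationError(f"design {design.design_id} not in profit matrix")
    series = profits.loc[design.design_id]
    return StrategyProfile(
        strategy=strategy,
        design_by_year={int(y): design.design_id for y in series.index},
        profits=series.astype(float),
        dsr_threshold=econ.dsr_threshold,
    )


def perfect_knowledge(
    profits: pd.DataFrame, designs: Sequence[CropDesign], econ: EconParams | None = None
) -> StrategyProfile:
    """Per-year profit-maximising design under observed weather."""
    econ = econ or EconParams()
    if profits.empty or not designs:
        raise OptimizationError("empty candidate set")
    order = _tie_break_order(designs)
    choice, real = {}, {}
    for year in profits.columns:
        col = profits[year].to_numpy()
        i = _argmax_with_ties(col, order)
        choice[int(year)] = designs[i].design_id
        real[int(year)] = float(col[i])
    return StrategyProfile(
        strategy="perfect_knowledge",
        design_by_year=choice,
        profits=pd.Series(real),
        dsr_threshold=econ.dsr_threshold,
    )


def select_forecast_designs(
    obs_profits: pd.DataFrame,  # design x year, observed weather (trace 0)
    ens_profits: pd.DataFrame,  # design x year, ensemble-mean profit
    bss_by_design: Mapping[str, float],
    designs: Sequence[CropDesign],
    econ: EconParams | None = None,
) -> StrategyProfile:
    """Forecast-informed dynamic strategy (the 4-step search).

    (i) the profit matrices are the design x strategy decision inputs;
    (ii) only designs with above/below-median yield-forecast BSS > 0 are
    candidates (fallback, flagged, to the full set's static optimum when
    none survives); (iii) per year, the surviving design with the highest
    ensemble-mean profit is chosen; (iv) its realised profit is the
    observed-weather profit of that year.
    """
    econ = econ or EconParams()
    if set(obs_profits.columns) != set(ens_profits.columns):
        raise InputError("observed and ensemble profit matrices must share years")
    surviving = [d for d in designs if bss_by_design.get(d.design_id, -1.0) > 0.0]
    if not surviving:
        prof = optimize_static(obs_profits, designs, econ)
        return StrategyProfile(
            strategy="forecast_optimal",
            design_by_year=prof.design_by_year,
            profits=prof.profits,
            dsr_threshold=econ.dsr_threshold,
            fallback=True,
        )
    order = _tie_break_order(surviving)
    ids = [d.design_id for d in surviving]
    choice, real = {}, {}
    for year in sorted(obs_profits.columns):
        col = ens_profits.loc[ids, year].to_numpy()
        i = _argmax_with_ties(col, order)
        did = ids[i]
        choice[int(year)] = did
        real[int(year)] = float(obs_profits.at[did, year])
    return StrategyProfile(
        strategy="forecast_optimal",
        design_by_year=choice,
        profits=pd.Series(real),
        dsr_threshold=econ.dsr_threshold,
    )


def value_report(
    farmer: StrategyProfile,
    static_optimal: StrategyProfile,
    forecast_optimal: StrategyProfile,
    pk: StrategyProfile,
    site: str = "",
    soil: str = "",
) -> ValueReport:
    """Assemble the three value numbers and DSR deltas from the four
    strategy profiles (all on the same year set)."""
    return ValueReport(
        site=site,
        soil=soil,
        farmer=farmer,
        static_optimal=static_optimal,
        forecast_optimal=forecast_optimal,
        perfect_knowledge=pk,
    )
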