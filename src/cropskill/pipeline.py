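"""Experiment orchestration: one config drives climate synthesis, both
forecast systems, the G x E x M factorial, verification and the value
analysis, with CSV artifacts, a run manifest and full seed-based
reproducibility.

The desk-scale default configuration (``default_reduced_config``) is a
reduced analogue of the full published factorial: one site, 3 soils,
5 sowing windows, 2 ISW levels, 2 densities, 2 N rates, 2 maturities,
2 tillering types, 2 row configurations, 35 hindcast years and 33 ensemble
members — 1,142,400 crop-year simulations — sized to complete on one CPU
in well under the verification-suite budget.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import climate, design_value, soi, verification
from .climate import ClimateGenParams, DailyWeatherSeries, EnsoIndexSeries
from .crop import (
    CropDesign,
    CropProxyParams,
    Environment,
    SoilProfile,
    month_label,
    month_number,
    simulate_yield_grid,
    thermal_time,
)
from .design_value import EconParams, StrategyProfile, ValueReport
from .errors import ConfigError, DependencyError, UndefinedMetricError
from .verification import EventDefinition

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "default_reduced_config",
    "run_pipeline",
    "reduced_paper_run",
    "simulate_yield_table",
    "verify_yields",
    "verify_rainfall",
    "compute_value",
]

STAGES = ("synth", "forecast", "simulate", "verify", "value")
_UPSTREAM = {
    "synth": (),
    "forecast": ("synth",),
    "simulate": ("synth",),
    "verify": ("simulate",),
    "value": ("simulate", "verify"),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    site_id: str = "Dalby"
    start_year: int = 1981
    n_years: int = 35
    seed: int = 1
    # climate generator
    annual_rain_mean: float = 650.0
    summer_fraction: float = 0.65
    teleconnection_strength: float = 0.6
    enso_ar1: float = 0.8
    # ensemble forecasts
    n_members: int = 33
    skill_rho: float = 0.5
    # factorial levels
    soils: dict = field(
        default_factory=lambda: {"high": 400.0, "medium": 344.0, "low": 274.0}
    )
    windows: list = field(
        default_factory=lambda: ["Sep", "Oct", "Nov", "Dec", "Jan"]
    )
    isw_levels: list = field(default_factory=lambda: [0.4, 0.6])
    densities: list = field(default_factory=lambda: [5.0, 8.0])
    n_rates: list = field(default_factory=lambda: [50.0, 100.0])
    maturities: list = field(default_factory=lambda: ["early", "medium"])
    tillerings: list = field(default_factory=lambda: ["medium", "high"])
    row_configs: list = field(default_factory=lambda: ["solid", "single_skip"])
    # farmer baseline (the published Dalby practice applied everywhere)
    farmer_window: str = "Oct"
    farmer_isw: float = 0.6
    farmer_maturity: str = "medium"
    farmer_tillering: str = "medium"
    farmer_density: float = 5.0
    farmer_row_config: str = "solid"
    farmer_n_rate: float = 50.0
    # economics
    econ: dict = field(
        default_factory=lambda: dataclasses.asdict(EconParams())
    )
    write_member_traces: bool = False

    def validate(self) -> "ExperimentConfig":
        try:
            if self.n_years < 3:
                raise ConfigError("n_years must be >= 3")
            if not 0.0 <= self.skill_rho <= 1.0:
                raise ConfigError("skill_rho must be in [0, 1]")
            if self.n_members < 2:
                raise ConfigError("n_members must be >= 2")
            for name in (
                "soils", "windows", "isw_levels", "densities", "n_rates",
                "maturities", "tillerings", "row_configs",
            ):
                if not getattr(self, name):
                    raise ConfigError(f"factor '{name}' has no levels")
            if self.farmer_window not in self.windows:
                raise ConfigError("farmer window must be a configured window")
            if self.farmer_isw not in self.isw_levels:
                raise ConfigError("farmer ISW must be a configured level")
            self.farmer_design()  # validates the design levels
            self.climate_params()
            self.econ_params()
        except ConfigError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap any parameter error
            raise ConfigError(str(exc)) from exc
        return self

    # --- derived objects ---------------------------------------------------

    def climate_params(self) -> ClimateGenParams:
        return ClimateGenParams(
            site_id=self.site_id,
            annual_rain_mean=self.annual_rain_mean,
            summer_fraction=self.summer_fraction,
            teleconnection_strength=self.teleconnection_strength,
            start_year=self.start_year,
            seed=self.seed,
        )

    def econ_params(self) -> EconParams:
        return EconParams(**self.econ)

    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def designs(self) -> list[CropDesign]:
        return [
            CropDesign(m, t, d, r, n)
            for m, t, d, r, n in itertools.product(
                self.maturities, self.tillerings, self.densities,
                self.row_configs, self.n_rates,
            )
        ]

    def soil_profiles(self) -> list[SoilProfile]:
        return [SoilProfile(label=k, pawc=v) for k, v in self.soils.items()]

    def environments(self) -> list[Environment]:
        return [
            Environment(self.site_id, s, isw, w)
            for s in self.soil_profiles()
            for isw in self.isw_levels
            for w in self.windows
        ]

    def farmer_design(self) -> CropDesign:
        return CropDesign(
            maturity=self.farmer_maturity,
            tillering=self.farmer_tillering,
            density=self.farmer_density,
            row_config=self.farmer_row_config,
            n_rate=self.farmer_n_rate,
        )

    # --- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "ExperimentConfig":
        text = str(path_or_text)
        if "\n" not in text:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def default_reduced_config(**overrides) -> ExperimentConfig:
    """The reduced desk-scale analogue of the published factorial."""
    return ExperimentConfig(**overrides).validate()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str] = field(default_factory=list)
    files: dict = field(default_factory=dict)  # filename -> data row count

    def save(self, out_dir: Path):
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, out_dir: Path) -> "RunManifest":
        p = Path(out_dir) / "manifest.json"
        if not p.exists():
            raise DependencyError(f"no manifest in {out_dir}; run upstream stages")
        return cls(**json.loads(p.read_text()))


# ---------------------------------------------------------------------------
# Stage computations (pure; file handling lives in run_pipeline)
# ---------------------------------------------------------------------------


def _issue_seed(seed: int, month: int, year: int) -> int:
    """Deterministic per-issue seed, independent of skill_rho so runs at
    different skill levels are paired draws."""
    return int(
        np.random.SeedSequence([seed, 104729, month, year]).generate_state(1)[0]
        % (2**31)
    )


def synthesize_climate(cfg: ExperimentConfig) -> tuple[EnsoIndexSeries, DailyWeatherSeries]:
    """Observed-weather stand-in (n_years + 1 calendar years, so late-window
    crops and forecast continuations stay covered) plus the ENSO index."""
    enso = climate.generate_enso_index(
        cfg.enso_ar1, cfg.n_years + 1, seed=cfg.seed + 11, start_year=cfg.start_year
    )
    obs = climate.generate_daily_weather(
        cfg.climate_params(), cfg.n_years + 1, enso=enso
    )
    return enso, obs


def ensemble_totals_table(
    cfg: ExperimentConfig, obs: DailyWeatherSeries, skill_rho: float | None = None
) -> pd.DataFrame:
    """Member window totals for every issue (window x year): the forecast
    archive at totals level. Matches segment 0 of the member seasons."""
    rho = cfg.skill_rho if skill_rho is None else skill_rho
    params = cfg.climate_params()
    rows = []
    for w in cfg.windows:
        month = month_number(w)
        totals = climate.window_totals(obs, month, 3)
        for year in cfg.years():
            fc = climate.generate_ensemble_forecast(
                obs,
                pd.Timestamp(year=year, month=month, day=1),
                rho,
                n_members=cfg.n_members,
                params=params,
                seed=climate.segment_seed(_issue_seed(cfg.seed, month, year), 0),
                include_traces=False,
                totals=totals,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "window": w,
                        "year": year,
                        "member": np.arange(1, cfg.n_members + 1),
                        "total": fc.totals,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_yield_table(
    cfg: ExperimentConfig,
    obs: DailyWeatherSeries,
    skill_rho: float | None = None,
    crop_params: CropProxyParams | None = None,
) -> pd.DataFrame:
    """The full factorial yield table: every (env, design, year, trace).

    Trace 0 is observed weather; traces 1..n_members are ensemble-member
    seasons at ``skill_rho``. Vectorised per sowing window over
    (env x design) x (year x trace).
    """
    rho = cfg.skill_rho if skill_rho is None else skill_rho
    params = cfg.climate_params()
    cp = crop_params or CropProxyParams()
    horizon = cp.horizon_days
    designs = cfg.designs()
    years = cfg.years()
    frames = []
    for w in cfg.windows:
        month = month_number(w)
        month_envs = [e for e in cfg.environments() if e.sowing_window == w]
        pairs = [(e, d) for e in month_envs for d in designs]
        from .crop import _case_arrays  # shared kernel plumbing

        case = _case_arrays(pairs, cp)
        scores_cache: dict = {}
        rain_rows, tt_rows, radn_rows, meta = [], [], [], []
        for year in years:
            issue = pd.Timestamp(year=year, month=month, day=1)
            sl = obs.slice(issue, issue + pd.Timedelta(days=horizon))
            rain_rows.append(sl["rain"].to_numpy()[:horizon])
            tt_rows.append(
                np.cumsum(thermal_time(sl["maxt"], sl["mint"], cp.base_temp))[:horizon]
            )
            radn_rows.append(sl["radn"].to_numpy()[:horizon])
            meta.append((year, 0))
            # crop-driving member seasons are conditioned month by month:
            # downscaled daily GCM traces carry sub-seasonal skill that a
            # single 3-month-total draw cannot (yields depend on rain timing
            # around grain fill)
            mem = climate.member_season_arrays(
                obs,
                issue,
                rho,
                cfg.n_members,
                params,
                seed=_issue_seed(cfg.seed, month, year),
                n_segments=6,
                segment_months=1,
                scores_cache=scores_cache,
            )
            tt_m = np.cumsum(
                thermal_time(mem["maxt"], mem["mint"], cp.base_temp), axis=1
            )
            for i in range(cfg.n_members):
                rain_rows.append(mem["rain"][i, :horizon])
                tt_rows.append(tt_m[i, :horizon])
                radn_rows.append(mem["radn"][i, :horizon])
                meta.append((year, i + 1))
        rain = np.stack(rain_rows)
        tt = np.stack(tt_rows)
        radn = np.stack(radn_rows)
        yields = simulate_yield_grid(rain, tt, radn, case, cp)
        n_combo, n_ty = yields.shape
        years_arr = np.array([m[0] for m in meta])
        traces_arr = np.array([m[1] for m in meta])

        def cat(vals):
            return pd.Categorical(np.repeat(vals, n_ty))

        frames.append(
            pd.DataFrame(
                {
                    "site": cat([e.site_id for e, _ in pairs]),
                    "soil": cat([e.soil.label for e, _ in pairs]),
                    "isw": np.repeat([e.isw_frac for e, _ in pairs], n_ty),
                    "window": cat([e.sowing_window for e, _ in pairs]),
                    "maturity": cat([d.maturity for _, d in pairs]),
                    "tillering": cat([d.tillering for _, d in pairs]),
                    "density": np.repeat([d.density for _, d in pairs], n_ty),
                    "row_config": cat([d.row_config for _, d in pairs]),
                    "n_rate": np.repeat([d.n_rate for _, d in pairs], n_ty),
                    "year": np.tile(years_arr, n_combo),
                    "trace": np.tile(traces_arr, n_combo),
                    "yield": yields.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["failed"] = out["yield"] < cp.failure_threshold
    return out


def verify_yields(cfg: ExperimentConfig, ytable: pd.DataFrame) -> pd.DataFrame:
    """Yield-event forecast skill per (soil, design, event) at the farmer
    environment (the decision-relevant slice of the factorial)."""
    sub = ytable[
        (ytable["window"] == cfg.farmer_window) & (ytable["isw"] == cfg.farmer_isw)
    ]
    res = verification.yield_event_skill(
        sub,
        group_cols=["soil"] + verification.DESIGN_COLS,
    )
    res.insert(
        0, "site", cfg.site_id
    )
    res["design_id"] = [
        CropDesign(r.maturity, r.tillering, r.density, r.row_config, r.n_rate).design_id
        for r in res.itertuples()
    ]
    return res


def verify_rainfall(
    cfg: ExperimentConfig,
    obs: DailyWeatherSeries,
    enso: EnsoIndexSeries,
    skill_rho: float | None = None,
    ens_totals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rainfall-event verification of both forecast systems, per window.

    For each issue month: ensemble probabilities from member window totals,
    analogue probabilities from the SOI-phase system (leave-one-out,
    climatology fallback flagged), outcomes from observed totals.
    """
    if ens_totals is None:
        ens_totals = ensemble_totals_table(cfg, obs, skill_rho=skill_rho)
    phases = soi.phase_table(enso)
    months = [month_number(w) for w in cfg.windows]
    clim = climate.compute_climatology(obs, [(m, 3) for m in months])
    rows = []
    for w, month in zip(cfg.windows, months):
        totals = climate.window_totals(obs, month, 3)
        stats = clim.window(month, 3)
        years = [y for y in cfg.years() if y in totals.index]
        obs_vals = totals[years].to_numpy()
        wtab = ens_totals[ens_totals["window"] == w]
        member_by_year = {
            y: g["total"].to_numpy() for y, g in wtab.groupby("year")
        }
        ana_probs = {}
        n_fallback = 0
        for y in years:
            fc = soi.analogue_forecast_or_climatology(
                obs, enso, month, y, clim, phases=phases, totals=totals
            )
            n_fallback += fc.fallback
            ana_probs[y] = fc.category_probs
        for kind in verification.EVENT_KINDS:
            ev = EventDefinition.from_window_stats(kind, stats)
            outs = verification.event_outcomes(obs_vals, ev)
            for system, probs in (
                (
                    "ensemble",
                    np.array(
                        [
                            verification.forecast_probability(member_by_year[y], ev)
                            for y in years
                        ]
                    ),
                ),
                (
                    "soi_phase",
                    np.array(
                        [
                            ana_probs[y][
                                kind if kind != "above_median" else "above_median"
                            ]
                            for y in years
                        ]
                    ),
                ),
            ):
                try:
                    bs, bs_ref, bss = verification.brier_skill_score(
                        probs, outs, ev.base_rate
                    )
                except UndefinedMetricError:
                    bs = bs_ref = bss = np.nan
                try:
                    pc = verification.percent_consistent(probs, outs, ev.base_rate)
                except UndefinedMetricError:
                    pc = np.nan
                if system == "ensemble":
                    amds, vrs = zip(
                        *(
                            verification.shift_dispersion(member_by_year[y], obs_vals)
                            for y in years
                        )
                    )
                    amd, vr = float(np.mean(amds)), float(np.mean(vrs))
                else:
                    amd = vr = np.nan
                rows.append(
                    {
                        "system": system,
                        "window": w,
                        "event": kind,
                        "n": len(years),
                        "BS": bs,
                        "BS_ref": bs_ref,
                        "BSS": bss,
                        "percent_consistent": pc,
                        "AMD": amd,
                        "VR": vr,
                        "n_fallback": n_fallback if system == "soi_phase" else 0,
                    }
                )
    return pd.DataFrame(rows)


def compute_value(
    cfg: ExperimentConfig,
    ytable: pd.DataFrame,
    yver: pd.DataFrame,
) -> tuple[list[ValueReport], pd.DataFrame, pd.DataFrame]:
    """Per-soil value reports, the Table-4-style summary, and the per-year
    strategy choice log, at the farmer environment."""
    econ = cfg.econ_params()
    designs = cfg.designs()
    reports: list[ValueReport] = []
    choice_rows = []
    for soil_label in cfg.soils:
        sub = ytable[
            (ytable["soil"] == soil_label)
            & (ytable["window"] == cfg.farmer_window)
            & (ytable["isw"] == cfg.farmer_isw)
        ]
        obs_mat = design_value.profit_matrix(sub, designs, econ, trace=0)
        ens_mat = design_value.profit_matrix(sub, designs, econ, trace=None)
        vsub = yver[(yver["soil"] == soil_label) & (yver["event"] == "above_median")]
        bss = dict(zip(vsub["design_id"], vsub["BSS"]))
        farmer = design_value.static_profile(obs_mat, cfg.farmer_design(), econ)
        static = design_value.optimize_static(obs_mat, designs, econ)
        fcst = design_value.select_forecast_designs(
            obs_mat, ens_mat, bss, designs, econ
        )
        pk = design_value.perfect_knowledge(obs_mat, designs, econ)
        rep = design_value.value_report(
            farmer, static, fcst, pk, site=cfg.site_id, soil=soil_label
        )
        reports.append(rep)
        for prof, mat in (
            (farmer, obs_mat),
            (static, obs_mat),
            (fcst, ens_mat),
            (pk, obs_mat),
        ):
            for year, did in sorted(prof.design_by_year.items()):
                choice_rows.append(
                    {
                        "soil": soil_label,
                        "year": year,
                        "strategy": prof.strategy,
                        "design_id": did,
                        "expected_profit": float(mat.at[did, year]),
                        "realized_profit": float(prof.profits[year]),
                    }
                )
    summary = pd.DataFrame([r.as_row() for r in reports])
    return reports, summary, pd.DataFrame(choice_rows)


# ---------------------------------------------------------------------------
# File-backed pipeline
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path, cfg: ExperimentConfig) -> int:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    return len(df)


def _load_csv(path: Path, manifest: RunManifest, stage_needed: str) -> pd.DataFrame:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path.name}; run stage '{stage_needed}' first"
        )
    df = pd.read_csv(path, comment="#")
    expected = manifest.files.get(path.name)
    if expected is not None and expected != len(df):
        raise DependencyError(
            f"{path.name} has {len(df)} rows, manifest says {expected}; "
            f"re-run stage '{stage_needed}'"
        )
    return df


def run_pipeline(
    config: ExperimentConfig,
    stages: Sequence[str] | None = None,
    out_dir=None,
) -> RunManifest:
    """Execute the requested stages in dependency order.

    Stages run in one call hand artifacts to each other in memory; a stage
    whose upstream ran in an earlier call reloads the CSVs and validates
    their row counts against the manifest (mismatch or absence raises
    :class:`DependencyError` naming the stage to re-run). Re-running with
    the same config and seed reproduces byte-identical CSV payloads.
    """
    cfg = config.validate()
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(out_dir) if out_dir is not None else Path("cropskill_run")
    out.mkdir(parents=True, exist_ok=True)
    try:
        manifest = RunManifest.load(out)
        if manifest.config_hash != cfg.config_hash():
            manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed)
    except DependencyError:
        manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed)

    ctx: dict = {}

    def need(stage: str):
        for up in _UPSTREAM[stage]:
            if up not in manifest.stages and up not in stages:
                raise DependencyError(
                    f"stage '{stage}' requires stage '{up}' which has not run"
                )

    for stage in stages:
        need(stage)
        if stage == "synth":
            enso, obs = synthesize_climate(cfg)
            ctx["enso"], ctx["obs"] = enso, obs
            climate.write_weather_csv(obs, out / "weather.csv", seed=cfg.seed)
            manifest.files["weather.csv"] = len(obs.data)
            enso_df = pd.DataFrame(
                {
                    "year": enso.values.index.year,
                    "month": enso.values.index.month,
                    "index": enso.values.to_numpy(),
                }
            )
            manifest.files["enso.csv"] = _write_csv(enso_df, out / "enso.csv", cfg)
            tot = ensemble_totals_table(cfg, obs)
            ctx["ens_totals"] = tot
            manifest.files["ensemble_totals.csv"] = _write_csv(
                tot, out / "ensemble_totals.csv", cfg
            )
            if cfg.write_member_traces:
                _write_member_traces(cfg, obs, out, manifest)
        elif stage == "forecast":
            enso, obs = _get_climate(cfg, ctx)
            phases = soi.phase_table(enso)
            manifest.files["phases.csv"] = _write_csv(
                phases, out / "phases.csv", cfg
            )
            months = sorted({month_number(w) for w in cfg.windows})
            clim = climate.compute_climatology(obs, [(m, 3) for m in months])
            rows = []
            for m in months:
                totals = climate.window_totals(obs, m, 3)
                for y in cfg.years():
                    if y not in totals.index:
                        continue
                    fc = soi.analogue_forecast_or_climatology(
                        obs, enso, m, y, clim, phases=phases, totals=totals
                    )
                    rows.append(
                        {
                            "window": month_label(m),
                            "year": y,
                            "phase": fc.phase,
                            "n_analogues": len(fc.analogue_years),
                            "fallback": fc.fallback,
                            **{f"p_{k}": v for k, v in fc.category_probs.items()},
                        }
                    )
            manifest.files["analogue_forecasts.csv"] = _write_csv(
                pd.DataFrame(rows), out / "analogue_forecasts.csv", cfg
            )
        elif stage == "simulate":
            _, obs = _get_climate(cfg, ctx)
            ytable = simulate_yield_table(cfg, obs)
            ctx["ytable"] = ytable
            manifest.files["yields.csv"] = _write_csv(ytable, out / "yields.csv", cfg)
        elif stage == "verify":
            ytable = ctx.get("ytable")
            if ytable is None:
                ytable = _load_csv(out / "yields.csv", manifest, "simulate")
                ctx["ytable"] = ytable
            yver = verify_yields(cfg, ytable)
            ctx["yver"] = yver
            manifest.files["verification_yield.csv"] = _write_csv(
                yver, out / "verification_yield.csv", cfg
            )
            enso, obs = _get_climate(cfg, ctx)
            rver = verify_rainfall(cfg, obs, enso, ens_totals=ctx.get("ens_totals"))
            manifest.files["verification_rain.csv"] = _write_csv(
                rver, out / "verification_rain.csv", cfg
            )
        elif stage == "value":
            ytable = ctx.get("ytable")
            if ytable is None:
                ytable = _load_csv(out / "yields.csv", manifest, "simulate")
            yver = ctx.get("yver")
            if yver is None:
                yver = _load_csv(out / "verification_yield.csv", manifest, "verify")
            reports, summary, choices = compute_value(cfg, ytable, yver)
            manifest.files["value_report.csv"] = _write_csv(
                summary, out / "value_report.csv", cfg
            )
            manifest.files["choices.csv"] = _write_csv(
                choices, out / "choices.csv", cfg
            )
        if stage not in manifest.stages:
            manifest.stages.append(stage)
        manifest.save(out)
    return manifest


def _get_climate(cfg, ctx):
    if "obs" not in ctx:
        ctx["enso"], ctx["obs"] = synthesize_climate(cfg)
    return ctx["enso"], ctx["obs"]


def _write_member_traces(cfg, obs, out: Path, manifest: RunManifest):
    """Optional per-issue daily member-trace archive plus an issue index."""
    params = cfg.climate_params()
    idx_rows = []
    tdir = out / "ensemble_traces"
    tdir.mkdir(exist_ok=True)
    for w in cfg.windows:
        month = month_number(w)
        for year in cfg.years():
            issue = pd.Timestamp(year=year, month=month, day=1)
            fc = climate.generate_ensemble_forecast(
                obs, issue, cfg.skill_rho, n_members=cfg.n_members, params=params,
                seed=climate.segment_seed(_issue_seed(cfg.seed, month, year), 0),
            )
            frames = []
            for i, m in enumerate(fc.members, start=1):
                f = m.reset_index(names="date")
                f.insert(0, "member", i)
                frames.append(f)
            df = pd.concat(frames, ignore_index=True)
            df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
            name = f"ensemble_traces/issue_{year}_{month:02d}.csv"
            manifest.files[name] = _write_csv(df, out / name, cfg)
            idx_rows.append({"window": w, "year": year, "file": name})
    manifest.files["ensemble_index.csv"] = _write_csv(
        pd.DataFrame(idx_rows), out / "ensemble_index.csv", cfg
    )


# ---------------------------------------------------------------------------
# In-memory reduced run
# ---------------------------------------------------------------------------


def reduced_paper_run(
    config: ExperimentConfig | None = None,
    seed: int | None = None,
    skill_rho: float | None = None,
) -> dict:
    """The reduced factorial end-to-end, entirely in memory.

    Returns a dict with the yield table, the yield-event verification rows
    (|soils| x |designs| x |events|), the per-soil :class:`ValueReport`
    list, the Table-4-style summary frame and the rainfall verification
    table.
    """
    cfg = config or default_reduced_config()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    if skill_rho is not None:
        cfg = dataclasses.replace(cfg, skill_rho=skill_rho)
    cfg.validate()
    enso, obs = synthesize_climate(cfg)
    ytable = simulate_yield_table(cfg, obs)
    yver = verify_yields(cfg, ytable)
    reports, summary, choices = compute_value(cfg, ytable, yver)
    rver = verify_rainfall(cfg, obs, enso)
    return {
        "config": cfg,
        "yields": ytable,
        "verification": yver,
        "value_reports": reports,
        "value_summary": summary,
        "choices": choices,
        "rain_verification": rver,
    }
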