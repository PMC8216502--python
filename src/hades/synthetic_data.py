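"""Synthetic study-input generators.

Emulates the four input sources of the study design — municipal annual
yield series with biennial bearing, daily weather, variety tables and
phenological observations — so the full pipeline runs and is testable
without any external download. The default configuration mirrors the
study dimensions: 7 units × 16 seasons (2004–2019), two regional groups
(a higher-yielding "west" and a lower-yielding, more strongly
alternating "east") in opposite alternation phase, one yield-shock year
paired with a late-frost event, and Black Sea-like seasonal weather.

Yields follow  y_t = μ_u (1 + (−1)^(t+φ_u) a_u) · shock_t + ε_t  with
ε ~ N(0, sd), floored at 0.01 t ha⁻¹: μ_u is the unit mean, a_u the
bienniality amplitude (intensity index of the noiseless series) and φ_u
the alternation phase. All generators are bit-reproducible given the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hazel_sim import HazelParams, SeasonSimulation, TRACKS, simulate_season
from .yield_stats import YieldSeries

__all__ = ["UnitSpec", "SyntheticStudyConfig", "default_config",
           "gen_yield_series", "gen_weather", "gen_phenology_obs",
           "gen_study"]

VARIETY_VOCAB = ["tombul", "palaz", "fosa", "cakildak", "mincane", "kara"]


@dataclass(frozen=True)
class UnitSpec:
    unit_id: str
    region: str            # "east" | "west" (two parameter groups)
    mean_yield: float      # mu_u, t ha-1
    amplitude: float       # a_u in [0, 1)
    phase: int             # 0/1: which parity of years is "on"
    temp_offset: float     # deg C added to the site temperature course
    varieties: tuple       # three main varieties

    def __post_init__(self):
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1)")
        if len(self.varieties) != 3:
            raise ValueError("exactly three varieties per unit")


@dataclass
class SyntheticStudyConfig:
    units: list
    start_year: int = 2004
    n_years: int = 16
    noise_sd: float = 0.05          # t ha-1, on official yields
    shocks: dict = field(default_factory=dict)   # unit_id -> {year: multiplier}
    # weather
    latitude: float = 41.0
    temp_mean: float = 14.0         # deg C annual mean
    temp_seasonal_amp: float = 9.0  # deg C, sinusoid amplitude
    temp_noise_sd: float = 2.0      # deg C daily noise
    diurnal_range: float = 8.0      # deg C mean tmax - tmin
    wet_day_prob: float = 0.4
    precip_scale: float = 6.0       # mm, exponential wet-day amount
    frost_events: list = field(default_factory=list)  # (unit_id, date, tmin)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for unit_id, per_year in self.shocks.items():
            for year, mult in per_year.items():
                if mult < 0:
                    raise ValueError("shock multiplier must be >= 0")
                if not (self.start_year <= year
                        < self.start_year + self.n_years):
                    raise ValueError(f"shock year {year} outside the study")
        seasons = range(self.start_year, self.start_year + self.n_years)
        for unit_id, date, tmin in self.frost_events:
            d = pd.Timestamp(date)
            season = d.year if d.month < 9 else d.year + 1
            if season not in seasons:
                raise ValueError(f"frost event {date} outside the study "
                                 "seasons")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


def default_config(seed: int = 0) -> SyntheticStudyConfig:
    """The default 7-unit × 16-season study bundle.

    Western units are higher-yielding with milder alternation; eastern
    units alternate more strongly, in opposite phase. One shock year
    (2014, eastern units) coincides with an injected late frost on
    April 6, 2014 — together they produce an unexpected off year.
    """
    units = [
        UnitSpec("sakarya", "west", 1.30, 0.16, 1, +0.5,
                 ("tombul", "palaz", "mincane")),
        UnitSpec("duzce", "west", 1.11, 0.16, 1, +0.3,
                 ("tombul", "fosa", "mincane")),
        UnitSpec("zonguldak", "west", 1.09, 0.17, 1, 0.0,
                 ("tombul", "cakildak", "kara")),
        UnitSpec("samsun", "east", 0.83, 0.20, 0, -0.3,
                 ("palaz", "cakildak", "tombul")),
        UnitSpec("ordu", "east", 0.70, 0.24, 0, -0.5,
                 ("palaz", "tombul", "kara")),
        UnitSpec("trabzon", "east", 0.70, 0.20, 0, -0.7,
                 ("tombul", "fosa", "cakildak")),
        UnitSpec("giresun", "east", 0.64, 0.31, 0, -0.5,
                 ("tombul", "palaz", "fosa")),
    ]
    shocks = {u.unit_id: {2014: 0.35} for u in units if u.region == "east"}
    frost = [(u.unit_id, "2014-04-06", -5.0) for u in units
             if u.region == "east"]
    return SyntheticStudyConfig(units=units, shocks=shocks,
                                frost_events=frost, seed=seed)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _rng(config: SyntheticStudyConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def gen_yield_series(config: SyntheticStudyConfig) -> list:
    """Annual official-yield series per unit (deterministic given seed)."""
    out = []
    for k, u in enumerate(config.units):
        rng = _rng(config, 1, k)
        t = np.arange(config.n_years)
        y = u.mean_yield * (1.0 + (-1.0) ** (t + u.phase) * u.amplitude)
        for year, mult in config.shocks.get(u.unit_id, {}).items():
            y[year - config.start_year] *= mult
        y = y + rng.normal(0.0, config.noise_sd, size=config.n_years)
        y = np.maximum(y, 0.01)
        out.append(YieldSeries(unit_id=u.unit_id, years=config.years,
                               yields=y))
    return out


def gen_weather(config: SyntheticStudyConfig, unit_id: str,
                season: int) -> pd.DataFrame:
    """Daily weather for one unit × season (Sep 1 → Aug 31), gap-free.

    Temperatures follow a seasonal sinusoid (minimum in mid-January) plus
    daily noise; precipitation is a wet-day Bernoulli draw with
    exponential amounts; relative humidity and wind speed are bounded
    draws. Configured frost events override tmin on their dates.
    """
    unit_ix = {u.unit_id: i for i, u in enumerate(config.units)}
    if unit_id not in unit_ix:
        raise ValueError(f"unknown unit {unit_id!r}")
    u = config.units[unit_ix[unit_id]]
    rng = _rng(config, 2, unit_ix[unit_id], season)
    dates = pd.date_range(pd.Timestamp(season - 1, 9, 1),
                          pd.Timestamp(season, 8, 31), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    tmean = (config.temp_mean + u.temp_offset
             - config.temp_seasonal_amp * np.cos(2 * np.pi * (doy - 15)
                                                 / 365.25)
             + rng.normal(0.0, config.temp_noise_sd, len(dates)))
    dtr = np.maximum(1.0, config.diurnal_range
                     + rng.normal(0.0, 1.5, len(dates)))
    tmin = tmean - dtr / 2.0
    tmax = tmean + dtr / 2.0
    wet = rng.random(len(dates)) < config.wet_day_prob
    precip = np.where(wet, rng.exponential(config.precip_scale, len(dates)),
                      0.0)
    rh = np.clip(70.0 + rng.normal(0.0, 10.0, len(dates))
                 + 10.0 * wet, 30.0, 100.0)
    wind = np.clip(rng.gamma(2.0, 5.0, len(dates)), 0.0, 80.0)
    w = pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmax,
                      "precip": precip, "rh": rh, "wind": wind})
    for ev_unit, ev_date, ev_tmin in config.frost_events:
        d = pd.Timestamp(ev_date)
        if ev_unit == unit_id and dates[0] <= d <= dates[-1]:
            i = (d - dates[0]).days
            w.loc[i, "tmin"] = ev_tmin
            w.loc[i, "tmax"] = max(w.loc[i, "tmax"], ev_tmin + 1.0)
    return w


def gen_phenology_obs(sim: SeasonSimulation, jitter_sd: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """Stage-onset observations from a simulated season, with day jitter.

    Observed date = simulated onset + integer Gaussian jitter; used for
    calibration self-recovery tests and the synthetic study bundle.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for track in TRACKS:
        for code, onset in sim.stage_onsets[track].items():
            jit = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
            rows.append({"unit_id": sim.unit_id, "season": sim.season,
                         "track": track, "stage_code": code,
                         "date": pd.Timestamp(onset) + pd.Timedelta(days=jit)})
    return pd.DataFrame(rows)


def gen_study(config: SyntheticStudyConfig, out_dir, overwrite: bool = False,
              params: HazelParams | None = None,
              phenology_seasons: tuple = (2018, 2019),
              phenology_jitter_sd: float = 0.0) -> dict:
    """Write the full input bundle (yields, weather, varieties, phenology).

    Produces, under ``out_dir``: yields.csv, varieties.csv,
    weather/<unit>.csv (all seasons concatenated, gap-free) and
    phenology.csv (simulated stage onsets for ``phenology_seasons`` under
    the given parameters, default parameters if none). Refuses to write
    into an existing non-empty directory unless ``overwrite`` is set.
    Returns the paths.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; "
                              "pass overwrite=True to replace it")
    (out / "weather").mkdir(parents=True, exist_ok=True)
    params = params or HazelParams(latitude=config.latitude)

    series = gen_yield_series(config)
    yields = pd.concat([
        pd.DataFrame({"unit_id": s.unit_id, "year": s.years,
                      "yield_t_ha": np.round(s.yields, 6)})
        for s in series
    ])
    yields.to_csv(out / "yields.csv", index=False)

    varieties = pd.DataFrame([
        {"unit_id": u.unit_id, "variety_1": u.varieties[0],
         "variety_2": u.varieties[1], "variety_3": u.varieties[2]}
        for u in config.units
    ])
    varieties.to_csv(out / "varieties.csv", index=False)

    weather_paths = {}
    pheno_frames = []
    for k, u in enumerate(config.units):
        frames = [gen_weather(config, u.unit_id, season)
                  for season in config.years]
        wu = pd.concat(frames, ignore_index=True)
        cols = {"tmin": "tmin_c", "tmax": "tmax_c", "precip": "precip_mm",
                "rh": "rh_pct", "wind": "wind_kmh"}
        wu.rename(columns=cols).to_csv(out / "weather" / f"{u.unit_id}.csv",
                                       index=False)
        weather_paths[u.unit_id] = out / "weather" / f"{u.unit_id}.csv"
        for season in phenology_seasons:
            if season not in config.years:
                raise ValueError(f"phenology season {season} outside study")
            sim = simulate_season(gen_weather(config, u.unit_id, season),
                                  params, onoff="on", unit_id=u.unit_id,
                                  season=season)
            pheno_frames.append(gen_phenology_obs(
                sim, jitter_sd=phenology_jitter_sd,
                seed=(config.seed & 0x7FFFFFFF) + 97 * k + season))
    pheno = pd.concat(pheno_frames, ignore_index=True)
    pheno["date"] = pd.to_datetime(pheno["date"]).dt.date
    pheno.to_csv(out / "phenology.csv", index=False)

    return {"yields": out / "yields.csv", "varieties": out / "varieties.csv",
            "weather": weather_paths, "phenology": out / "phenology.csv"}
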