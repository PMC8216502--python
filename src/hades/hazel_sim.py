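"""Process-based single-season hazelnut phenology and growth simulator.

The simulated season runs from September 1 (end of the previous cropping
season) to August 31 (harvest / prediction date). Each day the model

1. accumulates chilling hours (air temperature in the 0–7 °C window,
   counted on a sinusoidal hourly reconstruction between tmin and tmax)
   until the chilling requirement releases dormancy, then accumulates
   forcing degree-days above a base temperature that advance three
   parallel phenophase tracks — vegetative (V1–V10, dormant buds to leaf
   drop), catkin (C1–C4, male flowers) and female/fruit (R1–R13, with
   R10 = ovary development, the onset of nut growth);
2. estimates global radiation from the diurnal temperature range when it
   is not provided, splits it into direct and diffuse components, and
   intercepts it with a Beer's-law canopy whose ground-cover fraction
   follows the orchard row geometry;
3. computes gross assimilation as a light-saturating response modulated
   by a temperature-optimum factor and a stomatal factor declining with
   vapor pressure deficit, subtracts Q10 maintenance respiration of the
   five organs and a growth-respiration fraction;
4. partitions net assimilate to leaves, fruits, stem, branches and roots
   with phase-dependent coefficients; in off years the fruit share is
   damped by the unit-specific on→off reduction coefficient (the
   shortfall is redistributed to the other organs); green LAI grows with
   specific leaf area times the leaf increment;
5. applies late-frost damage: a kill fraction equal to stage
   susceptibility (ramping from female flowering to ovary enlarging)
   times frost severity in tmin, multiplying a season survival fraction
   that scales the final yield.

Calibration adjusts chosen parameters with a multi-start Nelder–Mead
simplex from Latin-hypercube starting points (phenology thresholds
against observed stage dates first, growth parameters against yields).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

__all__ = [
    "TRACKS", "ORGANS", "HazelParams", "SeasonSimulation",
    "estimate_radiation", "chilling_hours", "degree_days",
    "intercepted_radiation", "daily_net_assimilation", "partition_and_grow",
    "frost_damage", "simulate_season", "run_phenology",
    "calibrate", "holdout_split", "validate_weather", "vapor_pressure_deficit",
]

# phenophase tracks: stage code lists, index 0 = first stage
TRACKS = {
    "V": [f"V{i}" for i in range(1, 11)],   # dormant buds ... leaf drop
    "C": [f"C{i}" for i in range(1, 5)],    # catkin (male flower) stages
    "R": [f"R{i}" for i in range(1, 14)],   # female flower / fruit stages
}
ORGANS = ("leaves", "fruits", "stem", "branches", "roots")

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


def _default_partition_table() -> dict:
    """Phase-dependent assimilate partitioning (fractions sum to 1).

    Keyed by the female/fruit-track stage reached ("R0" = before R1).
    Fruit share is zero before ovary development (R10) and peaks during
    nut filling.
    """
    t = {}
    winter = dict(leaves=0.0, fruits=0.0, stem=0.35, branches=0.25, roots=0.40)
    for k in ("R0", "R1", "R2", "R3"):
        t[k] = dict(winter)
    spring = dict(leaves=0.35, fruits=0.0, stem=0.25, branches=0.15, roots=0.25)
    for k in ("R4", "R5", "R6"):
        t[k] = dict(spring)
    leafy = dict(leaves=0.50, fruits=0.0, stem=0.20, branches=0.10, roots=0.20)
    for k in ("R7", "R8", "R9"):
        t[k] = dict(leafy)
    t["R10"] = dict(leaves=0.30, fruits=0.30, stem=0.15, branches=0.10, roots=0.15)
    t["R11"] = dict(leaves=0.20, fruits=0.45, stem=0.15, branches=0.08, roots=0.12)
    t["R12"] = dict(leaves=0.10, fruits=0.60, stem=0.12, branches=0.08, roots=0.10)
    t["R13"] = dict(leaves=0.05, fruits=0.50, stem=0.20, branches=0.10, roots=0.15)
    return t


def _default_thresholds() -> dict:
    """Cumulative forcing thresholds (°C·d from dormancy release) per stage.

    Tuned so that, under a Black Sea-like seasonal temperature course,
    female flowering (R4) falls in mid-winter, ovary development (R10) in
    April, nut clusters visible (R12) in May and immature fruit (R13) in
    July — the phenological sequence the model is meant to reproduce.
    """
    return {
        "V": np.array([100, 180, 260, 350, 450, 600, 800, 1100, 1500, 2100],
                      dtype=float),
        "C": np.array([5, 15, 30, 60], dtype=float),
        "R": np.array([5, 10, 15, 25, 50, 100, 150, 200, 250, 300, 420, 600,
                       1300], dtype=float),
    }


@dataclass
class HazelParams:
    """Simulator parameters (units in comments; defaults are orchard-scale)."""

    # phenology
    chilling_req: float = 700.0          # h in the 0-7 °C window
    t_base: float = 5.0                  # °C, forcing base temperature
    forcing_thresholds: dict = field(default_factory=_default_thresholds)
    # frost window anchors on the female/fruit track
    frost_window_start: str = "R4"       # female flowering
    frost_window_end: str = "R11"        # ovary enlarging (peak susceptibility)
    fruit_onset_stage: str = "R10"       # ovary development: nut growth starts
    # assimilation / conductance
    amax: float = 0.012                  # kg DM m-2 d-1, max gross assimilation
    lue: float = 0.0022                  # kg DM MJ-1, initial light-response slope
    t_opt: float = 22.0                  # °C, temperature optimum
    t_width: float = 12.0                # °C, breadth of the optimum curve
    vpd_sens: float = 0.25               # kPa-1, stomatal decline with VPD
    # respiration
    q10: float = 2.0
    maint_coeff: dict = field(default_factory=lambda: dict(
        leaves=0.010, fruits=0.010, stem=0.0015, branches=0.002, roots=0.002))
    growth_resp_frac: float = 0.25
    # partitioning / canopy
    partition_table: dict = field(default_factory=_default_partition_table)
    sla: float = 15.0                    # m2 kg-1
    k_direct: float = 0.6
    k_diffuse: float = 0.7
    row_spacing: float = 4.5             # m
    plant_spacing: float = 3.0           # m
    plant_height: float = 3.0            # m
    crown_size: float = 2.5              # m (crown diameter)
    lai_init_coeff: float = 0.08         # m-2: LAI0 = c * height * crown
    init_biomass: dict = field(default_factory=lambda: dict(
        stem=0.8, branches=0.4, roots=0.6))  # kg m-2 structural at season start
    # frost response
    frost_t_nodamage: float = -1.0       # °C, tmin above this: no damage
    frost_t_full: float = -7.0           # °C, tmin at/below this: full kill
    # alternate bearing
    offyear_coeff: float = 1.0           # fruit-partition multiplier in off years
    # site
    latitude: float = 41.0               # degrees, for radiation estimation

    def __post_init__(self):
        if self.chilling_req < 0:
            raise ValueError("chilling_req must be >= 0")
        if not (self.frost_t_full < self.frost_t_nodamage):
            raise ValueError("frost_t_full must be below frost_t_nodamage")
        if not (0 < self.offyear_coeff <= 1):
            raise ValueError("offyear_coeff must be in (0, 1]")
        for key, fr in self.partition_table.items():
            s = sum(fr.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"partition fractions for {key} sum to {s}")

    # --- flat parameter access for calibration -------------------------
    def get_path(self, path: str):
        obj = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = obj[p] if isinstance(obj, dict) else (
                obj[int(p)] if isinstance(obj, np.ndarray) else getattr(obj, p))
        last = parts[-1]
        if isinstance(obj, dict):
            return obj[last]
        if isinstance(obj, np.ndarray):
            return float(obj[int(last)])
        return getattr(obj, last)

    def set_path(self, path: str, value: float) -> None:
        obj = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = obj[p] if isinstance(obj, dict) else (
                obj[int(p)] if isinstance(obj, np.ndarray) else getattr(obj, p))
        last = parts[-1]
        if isinstance(obj, dict):
            obj[last] = value
        elif isinstance(obj, np.ndarray):
            obj[int(last)] = value
        else:
            setattr(obj, last, value)

    def copy(self) -> "HazelParams":
        import copy as _copy
        return _copy.deepcopy(self)


@dataclass
class SeasonSimulation:
    """Daily trajectory and summary of one unit × season run."""

    unit_id: str
    season: int                      # harvest year (season = Sep 1 of season-1 .. Aug 31)
    daily: pd.DataFrame              # per-day state
    stage_onsets: dict               # track -> {stage_code: onset date}
    final_yield: float               # t ha-1 at August 31
    survival: float                  # season frost-survival fraction


# ---------------------------------------------------------------------------
# weather helpers
# ---------------------------------------------------------------------------

def validate_weather(weather: pd.DataFrame, season: int | None = None) -> pd.DataFrame:
    """Check daily-weather invariants; with ``season``, check Sep 1→Aug 31 coverage."""
    req = {"date", "tmin", "tmax", "precip", "rh", "wind"}
    missing = req - set(weather.columns)
    if missing:
        raise ValueError(f"weather missing columns: {sorted(missing)}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w = w.sort_values("date").reset_index(drop=True)
    if (w["tmin"] > w["tmax"]).any():
        bad = w.loc[w["tmin"] > w["tmax"], "date"].iloc[0]
        raise ValueError(f"tmin > tmax on {bad.date()}")
    if (w["precip"] < 0).any() or (w["wind"] < 0).any():
        raise ValueError("negative precipitation or wind")
    if ((w["rh"] < 0) | (w["rh"] > 100)).any():
        raise ValueError("relative humidity outside [0, 100]")
    if "rad" in w.columns and (w["rad"].dropna() < 0).any():
        raise ValueError("negative radiation")
    if season is not None:
        start = pd.Timestamp(season - 1, 9, 1)
        end = pd.Timestamp(season, 8, 31)
        expected = pd.date_range(start, end, freq="D")
        have = pd.DatetimeIndex(w["date"])
        gaps = expected.difference(have)
        if len(gaps):
            shown = ", ".join(str(d.date()) for d in gaps[:5])
            raise ValueError(f"weather gaps in season {season}: {shown}"
                             + ("..." if len(gaps) > 5 else ""))
        w = w[(w["date"] >= start) & (w["date"] <= end)].reset_index(drop=True)
    return w


def extraterrestrial_radiation(doy, latitude: float):
    """Top-of-atmosphere daily radiation (MJ m⁻² d⁻¹), FAO-56 formulation."""
    if not -90 <= latitude <= 90:
        raise ValueError("latitude must be in [-90, 90]")
    doy = np.asarray(doy, dtype=float)
    phi = math.radians(latitude)
    dr = 1 + 0.033 * np.cos(2 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24 * 60 / np.pi) * _SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    return np.maximum(ra, 0.0)


# clearness bounds: kt rises from KT_MIN (overcast, zero diurnal range)
# toward KT_MAX (clear sky) as the diurnal temperature range widens
KT_MIN, KT_MAX, KT_RATE = 0.10, 0.75, 0.15


def estimate_radiation(weather: pd.DataFrame, latitude: float) -> np.ndarray:
    """Estimate daily global radiation from the diurnal temperature range.

    rad = Ra × clearness, with clearness a saturating increasing function
    of (tmax − tmin) bounded by (KT_MIN, KT_MAX]: wide diurnal ranges mean
    clear skies, a zero range means heavy overcast.
    """
    dates = pd.to_datetime(weather["date"])
    doy = dates.dt.dayofyear.to_numpy()
    dtr = (weather["tmax"] - weather["tmin"]).to_numpy(dtype=float)
    if (dtr < 0).any():
        raise ValueError("tmax < tmin in weather input")
    ra = extraterrestrial_radiation(doy, latitude)
    kt = KT_MIN + (KT_MAX - KT_MIN) * (1.0 - np.exp(-KT_RATE * dtr))
    return ra * kt


def chilling_hours(tmin: float, tmax: float,
                   lo: float = 0.0, hi: float = 7.0) -> float:
    """Hours of the day with air temperature in the [lo, hi] chilling window.

    Hourly temperature is reconstructed as a symmetric 24-h sinusoid
    between tmin and tmax; the time-in-window has a closed form via the
    arcsine distribution of a sinusoid.
    """
    m = 0.5 * (tmin + tmax)
    a = 0.5 * (tmax - tmin)
    if a == 0.0:
        return 24.0 if lo <= m <= hi else 0.0

    def frac_below(x):
        s = (x - m) / a
        if s <= -1.0:
            return 0.0
        if s >= 1.0:
            return 1.0
        return 0.5 + math.asin(s) / math.pi

    return 24.0 * (frac_below(hi) - frac_below(lo))


def degree_days(tmin: float, tmax: float, t_base: float) -> float:
    """Daily forcing: max(0, daily mean temperature − base)."""
    return max(0.0, 0.5 * (tmin + tmax) - t_base)


def vapor_pressure_deficit(tmin: float, tmax: float, rh: float) -> float:
    """Daily VPD (kPa) from the temperature extremes and mean RH."""
    def es(t):
        return 0.6108 * math.exp(17.27 * t / (t + 237.3))
    es_mean = 0.5 * (es(tmin) + es(tmax))
    ea = rh / 100.0 * es_mean
    return max(0.0, es_mean - ea)


# ---------------------------------------------------------------------------
# daily process steps
# ---------------------------------------------------------------------------

@dataclass
class _SimState:
    chill: float = 0.0
    released: bool = False
    forcing: float = 0.0
    stage_idx: dict = field(default_factory=lambda: {"V": 0, "C": 0, "R": 0})
    lai: float = 0.0
    biomass: dict = field(default_factory=lambda: {o: 0.0 for o in ORGANS})
    survival: float = 1.0

    def stage_code(self, track: str) -> str:
        i = self.stage_idx[track]
        return f"{track}0" if i == 0 else TRACKS[track][i - 1]


def advance_phenology(state: _SimState, tmin: float, tmax: float,
                      params: HazelParams, date: pd.Timestamp,
                      onsets: dict) -> None:
    """One day of chilling / forcing accumulation and stage advancement.

    Chilling hours accumulate until the requirement releases dormancy;
    thereafter forcing degree-days accumulate and each track advances when
    its cumulative forcing crosses the next stage threshold. Stages never
    regress; onset dates are recorded once per stage.
    """
    if not state.released:
        state.chill += chilling_hours(tmin, tmax)
        if state.chill >= params.chilling_req:
            state.released = True
    if state.released:
        state.forcing += degree_days(tmin, tmax, params.t_base)
        for track, thresholds in params.forcing_thresholds.items():
            codes = TRACKS[track]
            while (state.stage_idx[track] < len(codes)
                   and state.forcing >= thresholds[state.stage_idx[track]]):
                state.stage_idx[track] += 1
                onsets[track][codes[state.stage_idx[track] - 1]] = date


def intercepted_radiation(lai: float, rad: float, diffuse_frac: float,
                          params: HazelParams) -> float:
    """Beer's-law canopy interception with orchard ground-cover geometry.

    f_cover = crown projected area / (row_spacing × plant_spacing), capped
    at 1; the leaf area is concentrated over the covered ground
    (lai_local = lai / f_cover). Direct and diffuse components use
    distinct extinction coefficients weighted by the diffuse fraction.
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    if rad <= 0 or lai == 0:
        return 0.0
    f_cover = min(1.0, params.crown_size ** 2
                  / (params.row_spacing * params.plant_spacing))
    lai_local = lai / f_cover
    absorbed = (diffuse_frac * (1.0 - math.exp(-params.k_diffuse * lai_local))
                + (1.0 - diffuse_frac)
                * (1.0 - math.exp(-params.k_direct * lai_local)))
    return rad * f_cover * absorbed


def daily_net_assimilation(intercepted: float, tmean: float, vpd: float,
                           biomass: dict, params: HazelParams) -> float:
    """Net daily assimilation (kg DM m⁻² d⁻¹); may be negative.

    gross = amax × (1 − exp(−lue·I/amax)) × f_T(tmean) × f_VPD(vpd):
    light-saturating in intercepted radiation I, a Gaussian optimum in
    temperature and a hyperbolic stomatal decline in VPD (hot, dry air
    during ripening depresses assimilation). Maintenance respiration is
    Q10-scaled per organ; the remainder is discounted by the
    growth-respiration fraction.
    """
    if intercepted < 0 or vpd < 0:
        raise ValueError("intercepted radiation and vpd must be >= 0")
    f_t = math.exp(-((tmean - params.t_opt) / params.t_width) ** 2)
    f_vpd = 1.0 / (1.0 + params.vpd_sens * vpd)
    if intercepted == 0.0:
        gross = 0.0
    else:
        gross = params.amax * (1.0 - math.exp(-params.lue * intercepted
                                              / params.amax)) * f_t * f_vpd
    q10_factor = params.q10 ** ((tmean - 20.0) / 10.0)
    maint = sum(biomass[o] * params.maint_coeff[o] for o in ORGANS) * q10_factor
    return (gross - maint) * (1.0 - params.growth_resp_frac)


def _partition_fractions(stage_code: str, onoff: str,
                         params: HazelParams) -> dict:
    try:
        fr = dict(params.partition_table[stage_code])
    except KeyError:
        raise ValueError(f"unknown partitioning stage {stage_code!r}")
    if onoff == "off" and fr["fruits"] > 0 and params.offyear_coeff < 1.0:
        shortfall = fr["fruits"] * (1.0 - params.offyear_coeff)
        fr["fruits"] -= shortfall
        others = [o for o in ORGANS if o != "fruits"]
        tot = sum(fr[o] for o in others)
        if tot > 0:
            for o in others:
                fr[o] += shortfall * fr[o] / tot
        else:
            fr["stem"] += shortfall
    return fr


def partition_and_grow(state: _SimState, net_assim: float, onoff: str,
                       params: HazelParams) -> dict:
    """Distribute the day's net assimilate over organs and grow LAI.

    Positive assimilate follows the phase table (keyed by the female/fruit
    stage reached); negative assimilate (respiration exceeding gross) is
    drawn from the non-fruit organs in proportion to their biomass —
    filled nuts are not resorbed — floored so no organ goes negative.
    Organ increments always sum to the (possibly floored) net
    assimilation. Returns the increments.
    """
    if onoff not in ("on", "off"):
        raise ValueError("onoff must be 'on' or 'off'")
    inc = {o: 0.0 for o in ORGANS}
    if net_assim >= 0.0:
        fr = _partition_fractions(state.stage_code("R"), onoff, params)
        for o in ORGANS:
            inc[o] = net_assim * fr[o]
    else:
        pool = [o for o in ORGANS if o != "fruits"]
        total = sum(state.biomass[o] for o in pool)
        draw = min(-net_assim, total)
        if total > 0:
            for o in pool:
                inc[o] = -draw * state.biomass[o] / total
    for o in ORGANS:
        state.biomass[o] = max(0.0, state.biomass[o] + inc[o])
    state.lai = max(0.0, state.lai + params.sla * inc["leaves"])
    return inc


def frost_damage(tmin: float, female_stage_idx: int,
                 params: HazelParams) -> float:
    """Daily kill fraction from late frost, in [0, 1].

    Susceptibility ramps linearly with the female-track stage from 0 at
    female flowering onset to 1 at ovary enlarging and is 0 outside that
    window; severity ramps linearly in tmin between the no-damage and
    full-kill thresholds.
    """
    codes = TRACKS["R"]
    i_start = codes.index(params.frost_window_start) + 1
    i_end = codes.index(params.frost_window_end) + 1
    s = female_stage_idx
    if s < i_start or s > i_end:
        susceptibility = 0.0
    else:
        susceptibility = (s - i_start) / (i_end - i_start) if i_end > i_start else 1.0
    if susceptibility == 0.0:
        return 0.0
    severity = (params.frost_t_nodamage - tmin) / (
        params.frost_t_nodamage - params.frost_t_full)
    severity = min(1.0, max(0.0, severity))
    return susceptibility * severity


# ---------------------------------------------------------------------------
# season loop
# ---------------------------------------------------------------------------

def simulate_season(weather: pd.DataFrame, params: HazelParams,
                    onoff: str = "on", unit_id: str = "unit",
                    season: int | None = None) -> SeasonSimulation:
    """Run the daily loop over one Sep 1 → Aug 31 season.

    ``weather`` must cover the season gap-free with columns date, tmin,
    tmax, precip, rh, wind and optionally rad (estimated from the diurnal
    temperature range when absent). Yield is dry nut biomass × 10
    (kg m⁻² → t ha⁻¹) scaled by the frost-survival fraction.
    Deterministic: identical inputs give identical output.
    """
    if season is None:
        season = int(pd.to_datetime(weather["date"]).max().year)
    w = validate_weather(weather, season=season)
    if "rad" not in w.columns or w["rad"].isna().any():
        w = w.copy()
        w["rad"] = estimate_radiation(w, params.latitude)
    ra = extraterrestrial_radiation(
        pd.to_datetime(w["date"]).dt.dayofyear.to_numpy(), params.latitude)
    kt = np.divide(w["rad"].to_numpy(dtype=float), ra,
                   out=np.zeros(len(w)), where=ra > 0)
    # diffuse fraction rises with cloudiness (low clearness)
    diffuse = np.clip(1.0 - kt / KT_MAX, 0.15, 1.0)

    state = _SimState()
    state.lai = params.lai_init_coeff * params.plant_height * params.crown_size
    state.biomass = {o: 0.0 for o in ORGANS}
    state.biomass["leaves"] = state.lai / params.sla
    for o, b in params.init_biomass.items():
        state.biomass[o] = float(b)

    onsets = {t: {} for t in TRACKS}
    rows = []
    for i, rec in enumerate(w.itertuples(index=False)):
        date = pd.Timestamp(rec.date)
        advance_phenology(state, rec.tmin, rec.tmax, params, date, onsets)
        tmean = 0.5 * (rec.tmin + rec.tmax)
        vpd = vapor_pressure_deficit(rec.tmin, rec.tmax, rec.rh)
        inter = intercepted_radiation(state.lai, float(w["rad"].iloc[i]),
                                      float(diffuse[i]), params)
        net = daily_net_assimilation(inter, tmean, vpd, state.biomass, params)
        inc = partition_and_grow(state, net, onoff, params)
        kill = frost_damage(rec.tmin, state.stage_idx["R"], params)
        if kill > 0.0:
            state.survival *= (1.0 - kill)
        rows.append({
            "date": date, "doy": date.dayofyear,
            "stage_V": state.stage_code("V"), "stage_C": state.stage_code("C"),
            "stage_R": state.stage_code("R"),
            "lai": state.lai,
            **{f"biomass_{o}": state.biomass[o] for o in ORGANS},
            "net_assim": net, "increment_total": sum(inc.values()),
            "survival": state.survival,
            "fruit_yield": state.biomass["fruits"] * state.survival * 10.0,
        })
    daily = pd.DataFrame(rows)
    return SeasonSimulation(unit_id=unit_id, season=season, daily=daily,
                            stage_onsets=onsets,
                            final_yield=float(daily["fruit_yield"].iloc[-1]),
                            survival=state.survival)


def run_phenology(weather: pd.DataFrame, params: HazelParams,
                  season: int | None = None) -> dict:
    """Phenology-only season run returning stage onset dates per track.

    Skips the growth processes; used by the phenology calibration phase
    where only onset dates enter the objective.
    """
    if season is None:
        season = int(pd.to_datetime(weather["date"]).max().year)
    w = validate_weather(weather, season=season)
    state = _SimState()
    onsets = {t: {} for t in TRACKS}
    tmin = w["tmin"].to_numpy(dtype=float)
    tmax = w["tmax"].to_numpy(dtype=float)
    dates = pd.to_datetime(w["date"])
    for i in range(len(w)):
        advance_phenology(state, tmin[i], tmax[i], params, dates.iloc[i],
                          onsets)
    return onsets


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold an unconstrained point into [lo, hi] by reflection at the bounds."""
    span = hi - lo
    out = lo.copy()
    free = span > 0
    y = np.mod(x[free] - lo[free], 2.0 * span[free])
    out[free] = lo[free] + np.minimum(y, 2.0 * span[free] - y)
    return out


@dataclass
class CalibrationResult:
    params: HazelParams
    param_names: list
    values: np.ndarray
    objective: float
    trace: list          # (start index, objective) per start
    improved: bool


def calibrate(objective, base_params: HazelParams, param_names: list,
              bounds: dict, n_starts: int = 5, seed: int = 0,
              maxiter: int = 200) -> CalibrationResult:
    """Multi-start Nelder–Mead simplex search over named parameters.

    ``objective(params) -> float`` is minimized (MAE in days for the
    phenology phase, MAE in t ha⁻¹ for the yield phase). Starting points
    are a Latin-hypercube sample of the box ``bounds`` (dict name →
    (lo, hi)); each simplex runs unconstrained with candidate points
    folded back into the box by reflection. Degenerate boxes (lo == hi)
    are honored: the search returns that point.
    """
    lo = np.array([bounds[n][0] for n in param_names], dtype=float)
    hi = np.array([bounds[n][1] for n in param_names], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("bounds must be finite")
    if np.any(hi < lo):
        raise ValueError("upper bound below lower bound")

    def make_params(values: np.ndarray) -> HazelParams:
        p = base_params.copy()
        for name, v in zip(param_names, values):
            p.set_path(name, float(v))
        return p

    def f(x: np.ndarray) -> float:
        return float(objective(make_params(_reflect(x, lo, hi))))

    span = hi - lo
    if np.all(span == 0):
        vals = lo.copy()
        return CalibrationResult(params=make_params(vals),
                                 param_names=list(param_names), values=vals,
                                 objective=f(vals), trace=[(0, f(vals))],
                                 improved=True)
    sampler = qmc.LatinHypercube(d=len(param_names), seed=seed)
    starts = lo + sampler.random(n_starts) * span
    best_x, best_f = None, math.inf
    trace = []
    for k, x0 in enumerate(starts):
        res = optimize.minimize(f, x0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-4,
                                         "fatol": 1e-6})
        trace.append((k, float(res.fun)))
        if res.fun < best_f:
            best_f, best_x = float(res.fun), _reflect(res.x, lo, hi)
    start_objs = [f(x0) for x0 in starts]
    if best_f > min(start_objs):
        warnings.warn("no simplex start improved on its initial point; "
                      "returning the best starting point")
        k = int(np.argmin(start_objs))
        best_x, best_f = starts[k], start_objs[k]
    return CalibrationResult(params=make_params(best_x),
                             param_names=list(param_names),
                             values=np.asarray(best_x), objective=best_f,
                             trace=trace, improved=True)


def phenology_mae(observations: pd.DataFrame, weather_by_season: dict,
                  params: HazelParams, miss_penalty: float = 60.0) -> float:
    """MAE in days between simulated and observed stage-onset dates.

    ``observations`` columns: season, track, stage_code, date. A stage
    the simulation never reaches contributes ``miss_penalty`` days.
    """
    errs = []
    for season, obs in observations.groupby("season"):
        onsets = run_phenology(weather_by_season[int(season)], params,
                               season=int(season))
        for rec in obs.itertuples(index=False):
            sim_date = onsets[rec.track].get(rec.stage_code)
            if sim_date is None:
                errs.append(miss_penalty)
            else:
                errs.append(abs((pd.Timestamp(rec.date) - sim_date).days))
    if not errs:
        raise ValueError("no observations")
    return float(np.mean(errs))


def yield_mae(observations: pd.DataFrame, weather_by_season: dict,
              params: HazelParams) -> float:
    """MAE in t ha⁻¹ between simulated and observed season yields.

    ``observations`` columns: season, onoff, yield_t_ha.
    """
    errs = []
    for rec in observations.itertuples(index=False):
        sim = simulate_season(weather_by_season[int(rec.season)], params,
                              onoff=rec.onoff, season=int(rec.season))
        errs.append(abs(sim.final_yield - rec.yield_t_ha))
    if not errs:
        raise ValueError("no observations")
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# stratified hold-out
# ---------------------------------------------------------------------------

def holdout_split(records: pd.DataFrame, seed: int = 0):
    """50/50 split stratified by (unit × on/off label).

    Per stratum the two halves differ by at most one record; singleton
    strata go to the calibration half with a warning. Returns
    (calibration, evaluation) DataFrames.
    """
    for col in ("unit_id", "onoff"):
        if col not in records.columns:
            raise ValueError(f"records must carry a {col!r} column")
    rng = np.random.default_rng(seed)
    cal_idx, eval_idx = [], []
    for (_, _), grp in records.groupby(["unit_id", "onoff"], sort=True):
        idx = grp.index.to_numpy()
        if len(idx) == 1:
            warnings.warn(f"stratum of size 1 assigned to calibration "
                          f"(unit {grp['unit_id'].iloc[0]}, "
                          f"{grp['onoff'].iloc[0]})")
            cal_idx.extend(idx)
            continue
        perm = rng.permutation(idx)
        half = len(perm) // 2 + (len(perm) % 2)  # calibration gets the odd one
        cal_idx.extend(perm[:half])
        eval_idx.extend(perm[half:])
    return records.loc[sorted(cal_idx)], records.loc[sorted(eval_idx)]
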