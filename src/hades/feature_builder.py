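"""Design-matrix construction for the machine-learning layer.

One row per unit × season with exactly 89 predictors: the unit's three
main varieties (categorical), the season's on/off label, the simulated
yield, and — for 14 phenological phases (R7–R13 on the female/fruit
track, V1–V7 on the vegetative track) — six agro-meteorological
indicators computed over each phase's onset-to-next-onset window:
minimum tmin, mean daily temperature, maximum tmax (°C), total
precipitation (mm), mean relative humidity (%) and maximum wind speed
(km h⁻¹). No window extends past August 31, so no within-season weather
"forecast" leaks into the predictors. The response column is the
official yield (yield_obs_t_ha).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .hazel_sim import TRACKS, SeasonSimulation

__all__ = ["FEATURE_PHASES", "INDICATORS", "predictor_columns",
           "phase_windows", "agro_indicators", "assemble_features"]

logger = logging.getLogger(__name__)

FEATURE_PHASES = [("R", f"R{i}") for i in range(7, 14)] + \
                 [("V", f"V{i}") for i in range(1, 8)]
INDICATORS = ["tmin_min", "tmean_avg", "tmax_max", "precip_total",
              "rh_mean", "wind_max"]


def predictor_columns() -> list:
    """The fixed, documented order of the 89 predictor columns."""
    cols = ["variety_1", "variety_2", "variety_3", "onoff_label",
            "hazel_yield"]
    for _, code in FEATURE_PHASES:
        for ind in INDICATORS:
            cols.append(f"{code}_{ind}")
    return cols


def phase_windows(sim: SeasonSimulation) -> dict:
    """Half-open date windows [onset, next onset) for the 14 feature phases.

    The next onset is the following stage's within the same track; the
    last phase (or one whose successor is never reached) is clipped at
    August 31 (exclusive end = September 1). A phase the season never
    reaches gets an empty window (None).
    """
    season_end = pd.Timestamp(sim.season, 9, 1)  # exclusive
    windows = {}
    for track, code in FEATURE_PHASES:
        onsets = sim.stage_onsets[track]
        start = onsets.get(code)
        if start is None:
            windows[code] = None
            continue
        codes = TRACKS[track]
        nxt = codes.index(code) + 1
        end = season_end
        if nxt < len(codes) and codes[nxt] in onsets:
            end = min(onsets[codes[nxt]], season_end)
        if start >= end:
            windows[code] = None
        else:
            windows[code] = (start, end)
    return windows


def agro_indicators(weather: pd.DataFrame, window) -> dict:
    """Six agro-meteorological indicators over a half-open date window.

    Returns NaNs for an empty (None) window.
    """
    if window is None:
        return {ind: np.nan for ind in INDICATORS}
    start, end = window
    dates = pd.to_datetime(weather["date"])
    mask = (dates >= start) & (dates < end)
    w = weather.loc[mask]
    if w.empty:
        raise ValueError(f"weather does not cover window {start.date()}"
                         f"..{end.date()}")
    return {
        "tmin_min": float(w["tmin"].min()),
        "tmean_avg": float(((w["tmin"] + w["tmax"]) / 2.0).mean()),
        "tmax_max": float(w["tmax"].max()),
        "precip_total": float(w["precip"].sum()),
        "rh_mean": float(w["rh"].mean()),
        "wind_max": float(w["wind"].max()),
    }


def assemble_features(varieties: pd.DataFrame, labels: pd.DataFrame,
                      sims: dict, weather_by_unit: dict,
                      official_yields: pd.DataFrame) -> pd.DataFrame:
    """Build the 89-predictor design matrix plus the response column.

    Parameters
    ----------
    varieties : DataFrame with columns unit_id, variety_1..variety_3.
    labels : DataFrame with columns unit_id, year, label ("on"/"off").
    sims : {(unit_id, season): SeasonSimulation}.
    weather_by_unit : {unit_id: multi-season daily weather DataFrame}.
    official_yields : DataFrame with columns unit_id, year, yield_t_ha.

    Rows lacking any source (no label, no simulation, no response) are
    dropped with a logged reason. Indicator NaNs from unreached phases are
    left in place for the ML layer's fold-wise imputation.
    """
    var_map = varieties.set_index("unit_id")
    lab_map = labels.set_index(["unit_id", "year"])["label"]
    y_map = official_yields.set_index(["unit_id", "year"])["yield_t_ha"]
    rows = []
    index = []
    for (unit, season), sim in sorted(sims.items()):
        key = (unit, season)
        if unit not in var_map.index:
            logger.warning("dropping %s/%s: no variety record", unit, season)
            continue
        if key not in lab_map.index or lab_map.loc[key] is None:
            logger.warning("dropping %s/%s: no on/off label", unit, season)
            continue
        if key not in y_map.index:
            logger.warning("dropping %s/%s: no official yield", unit, season)
            continue
        row = {
            "variety_1": var_map.loc[unit, "variety_1"],
            "variety_2": var_map.loc[unit, "variety_2"],
            "variety_3": var_map.loc[unit, "variety_3"],
            "onoff_label": lab_map.loc[key],
            "hazel_yield": sim.final_yield,
        }
        windows = phase_windows(sim)
        weather = weather_by_unit[unit]
        for _, code in FEATURE_PHASES:
            ind = agro_indicators(weather, windows[code])
            for name, val in ind.items():
                row[f"{code}_{name}"] = val
        row["yield_obs_t_ha"] = float(y_map.loc[key])
        rows.append(row)
        index.append(key)
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index or [("", 0)], names=["unit_id", "season"])[: len(rows)])
    cols = predictor_columns() + ["yield_obs_t_ha"]
    table = table.reindex(columns=cols)
    assert len(predictor_columns()) == 89
    return table
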