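"""Shared I/O, run configuration and the end-to-end pipeline.

File formats (all plain CSV, ISO-8601 dates):

* yields: ``unit_id, year, yield_t_ha`` or ``unit_id, year, production_t,
  area_dekare`` (yield derived as production / (area/10); 10 dekare = 1 ha);
* weather, one file per unit: ``date, tmin_c, tmax_c, precip_mm, rh_pct,
  wind_kmh[, rad_mj_m2]``;
* varieties: ``unit_id, variety_1, variety_2, variety_3``;
* phenology observations: ``unit_id, season, track, stage_code, date``.

``run_pipeline`` wires the three analysis steps together: yield
statistics → per unit × season growth simulation (with the on/off label
and off-year reduction coefficient from step 1) → feature assembly →
random-forest prediction, writing every artifact plus a manifest with
the echoed configuration, seeds, versions and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import yield_stats
from .feature_builder import assemble_features
from .hazel_sim import HazelParams, simulate_season, validate_weather
from .ml_layer import RFConfig, run_prediction
from .yield_stats import YieldSeries, summarize_bienniality

__all__ = ["RunConfig", "read_yield_csv", "read_weather_csv",
           "write_weather_csv", "read_varieties_csv", "read_phenology_csv",
           "run_pipeline"]

logger = logging.getLogger(__name__)

WEATHER_COLS = {"date": "date", "tmin_c": "tmin", "tmax_c": "tmax",
                "precip_mm": "precip", "rh_pct": "rh", "wind_kmh": "wind",
                "rad_mj_m2": "rad"}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_yield_csv(path) -> list:
    """Parse a yield CSV into validated per-unit YieldSeries.

    Accepts either a ``yield_t_ha`` column or the ``production_t`` +
    ``area_dekare`` pair (converted via 10 dekare = 1 ha). Rows may be
    unsorted; duplicate (unit, year) pairs and non-consecutive years are
    rejected with the offending values named.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty yield file")
    base = {"unit_id", "year"}
    if not base <= set(df.columns):
        raise ValueError(f"{path}: need columns unit_id, year")
    if "yield_t_ha" in df.columns:
        df = df[["unit_id", "year", "yield_t_ha"]].copy()
    elif {"production_t", "area_dekare"} <= set(df.columns):
        df = df[["unit_id", "year", "production_t", "area_dekare"]].copy()
        df["yield_t_ha"] = df["production_t"] / (df["area_dekare"] / 10.0)
    else:
        raise ValueError(f"{path}: need yield_t_ha or "
                         "production_t + area_dekare columns")
    dup = df.duplicated(subset=["unit_id", "year"])
    if dup.any():
        bad = df.loc[dup, ["unit_id", "year"]].to_records(index=False)
        raise ValueError(f"{path}: duplicate (unit, year) rows: {list(bad)[:5]}")
    out = []
    for unit, grp in df.groupby("unit_id", sort=True):
        grp = grp.sort_values("year")
        out.append(YieldSeries(unit_id=str(unit),
                               years=grp["year"].to_numpy(),
                               yields=grp["yield_t_ha"].to_numpy()))
    return out


def read_weather_csv(path) -> pd.DataFrame:
    """Read one unit's daily weather into the internal column layout."""
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLS if c != "rad_mj_m2"
               and c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing weather columns {missing}")
    df = df.rename(columns=WEATHER_COLS)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as e:
        raise ValueError(f"{path}: unparseable dates ({e})") from None
    return validate_weather(df)


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    """Write weather in the external layout (round-trip stable)."""
    inv = {v: k for k, v in WEATHER_COLS.items()}
    out = weather.rename(columns=inv).copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def read_varieties_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"unit_id", "variety_1", "variety_2", "variety_3"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    return df


def read_phenology_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"unit_id", "season", "track", "stage_code", "date"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full pipeline configuration with explicit per-stage seeds."""

    yields_path: str = "yields.csv"
    weather_dir: str = "weather"
    varieties_path: str = "varieties.csv"
    out_dir: str = "out"
    # yield statistics
    n_boot: int = 5000
    n_perm: int = 5000
    istar_pool: str = "series"
    stats_seed: int = 12061
    # simulator parameter overrides, flat "path: value" (see HazelParams)
    sim_params: dict = field(default_factory=dict)
    # machine-learning layer
    n_splits: int = 100
    n_trees: int = 500
    loocv: bool = True
    ml_seed: int = 12062
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _seed_first_year(labels: list) -> list:
    """Give the first season the label opposite to a data-derived year 2.

    The labeling rule never labels year 1 from data; for a full unit ×
    season prediction grid the pipeline seeds it by alternation when the
    second year's label is data-derived.
    """
    labels = list(labels)
    if labels[0] is None and labels[1] in ("on", "off"):
        labels[0] = "off" if labels[1] == "on" else "on"
    return labels


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute yield statistics → simulation → features → prediction.

    Writes, under ``config.out_dir``: yield_summary.csv,
    yield_labels.csv, simulated_yields.csv, features.csv,
    split_metrics.csv, median_metrics.json, importance.csv,
    error_table.csv and manifest.json. Returns the report and paths.
    Any stage failure raises with the stage named.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "yield_stats"
    try:
        series = read_yield_csv(config.yields_path)
        summaries = {}
        label_rows, summary_rows = [], []
        for s in series:
            summ = summarize_bienniality(s, n_boot=config.n_boot,
                                         n_perm=config.n_perm,
                                         seed=config.stats_seed,
                                         pool=config.istar_pool)
            summ.labels = _seed_first_year(summ.labels)
            summaries[s.unit_id] = (s, summ)
            trend = yield_stats.trend_test(s)
            summary_rows.append({
                "unit_id": s.unit_id, "mean": float(np.mean(s.yields)),
                "sd": float(np.std(s.yields, ddof=1)), "slope": trend.slope,
                "mk_p": trend.mk_p, "B": summ.B, "I": summ.I,
                "exceedance_freq": summ.I_exceedance_freq,
                "I0001": summ.I0001,
                "offyear_coeff": yield_stats.onoff_reduction(s, summ.labels),
            })
            for i, year in enumerate(s.years):
                label_rows.append({
                    "unit_id": s.unit_id, "year": int(year),
                    "yield_t_ha": float(s.yields[i]),
                    "istar": float(summ.istar[i - 1]) if i > 0 else np.nan,
                    "label": summ.labels[i],
                    "unexpected": bool(summ.unexpected[i]),
                })
        summary_df = pd.DataFrame(summary_rows)
        labels_df = pd.DataFrame(label_rows)
        summary_df.to_csv(out / "yield_summary.csv", index=False)
        labels_df.to_csv(out / "yield_labels.csv", index=False)

        stage = "hazel_sim"
        weather_by_unit, sims = {}, {}
        sim_rows = []
        for s in series:
            _, summ = summaries[s.unit_id]
            wpath = Path(config.weather_dir) / f"{s.unit_id}.csv"
            if not wpath.exists():
                raise FileNotFoundError(f"no weather file for {s.unit_id}: "
                                        f"{wpath}")
            weather = read_weather_csv(wpath)
            weather_by_unit[s.unit_id] = weather
            params = HazelParams()
            coeff = next(r["offyear_coeff"] for r in summary_rows
                         if r["unit_id"] == s.unit_id)
            params.offyear_coeff = float(coeff)
            for key, val in config.sim_params.items():
                params.set_path(key, val)
            for i, year in enumerate(s.years):
                label = summaries[s.unit_id][1].labels[i]
                if label is None:
                    logger.warning("skipping %s/%s: no on/off label",
                                   s.unit_id, year)
                    continue
                sim = simulate_season(weather, params, onoff=label,
                                      unit_id=s.unit_id, season=int(year))
                sims[(s.unit_id, int(year))] = sim
                sim_rows.append({"unit_id": s.unit_id, "season": int(year),
                                 "onoff": label,
                                 "sim_yield_t_ha": sim.final_yield,
                                 "survival": sim.survival})
        pd.DataFrame(sim_rows).to_csv(out / "simulated_yields.csv",
                                      index=False)

        stage = "feature_builder"
        varieties = read_varieties_csv(config.varieties_path)
        labels_for_features = labels_df.rename(columns={"label": "label"})[
            ["unit_id", "year", "label"]]
        official = labels_df[["unit_id", "year", "yield_t_ha"]]
        table = assemble_features(varieties, labels_for_features, sims,
                                  weather_by_unit, official)
        table.to_csv(out / "features.csv")

        stage = "ml_layer"
        rf_config = RFConfig(n_trees=config.n_trees, loocv=config.loocv)
        report = run_prediction(table, n_splits=config.n_splits,
                                seed=config.ml_seed, config=rf_config)
        report.per_split_validation.to_csv(out / "split_metrics.csv")
        with open(out / "median_metrics.json", "w") as fh:
            json.dump({"validation": report.median_validation,
                       "calibration": report.median_calibration}, fh,
                      indent=2)
        report.importance.to_csv(out / "importance.csv", index=False)
        report.errors.to_csv(out / "error_table.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    from . import __version__
    artifacts = ["yield_summary.csv", "yield_labels.csv",
                 "simulated_yields.csv", "features.csv", "split_metrics.csv",
                 "median_metrics.json", "importance.csv", "error_table.csv"]
    manifest = {
        "config": config.echo(),
        "seeds": {"stats": config.stats_seed, "ml": config.ml_seed},
        "versions": {"hades": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "checksums": {a: _sha256(out / a) for a in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"report": report, "features": table, "summary": summary_df,
            "labels": labels_df, "out_dir": out}
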