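"""Shared fixtures: in-memory synthetic study bundles.

The session-scoped ``default_bundle`` replicates the pipeline in memory
on the default 7-unit × 16-season configuration: yield statistics with
on/off labels (first season seeded by alternation), one season
simulation per labeled unit × season, and the assembled 89-predictor
feature table.
"""

import pandas as pd
import pytest

from hades.feature_builder import assemble_features
from hades.hazel_sim import HazelParams, simulate_season
from hades.io import _seed_first_year
from hades.synthetic_data import default_config, gen_weather, gen_yield_series
from hades.yield_stats import onoff_reduction, summarize_bienniality

BUNDLE_SEED = 20


def build_bundle(config, n_boot=5000, n_perm=5000, stats_seed=101):
    """Build yields, labels, sims and the feature table in memory."""
    series = gen_yield_series(config)
    summaries, label_rows, coeffs = {}, [], {}
    for s in series:
        summ = summarize_bienniality(s, n_boot=n_boot, n_perm=n_perm,
                                     seed=stats_seed)
        summ.labels = _seed_first_year(summ.labels)
        summaries[s.unit_id] = summ
        try:
            coeffs[s.unit_id] = onoff_reduction(s, summ.labels)
        except ValueError:
            coeffs[s.unit_id] = 1.0
        for i, year in enumerate(s.years):
            label_rows.append({"unit_id": s.unit_id, "year": int(year),
                               "label": summ.labels[i],
                               "yield_t_ha": float(s.yields[i])})
    labels_df = pd.DataFrame(label_rows)
    weather_by_unit, sims = {}, {}
    for s in series:
        frames = [gen_weather(config, s.unit_id, int(season))
                  for season in s.years]
        weather_by_unit[s.unit_id] = pd.concat(frames, ignore_index=True)
        params = HazelParams(latitude=config.latitude,
                             offyear_coeff=coeffs[s.unit_id])
        for i, year in enumerate(s.years):
            label = summaries[s.unit_id].labels[i]
            if label is None:
                continue
            sims[(s.unit_id, int(year))] = simulate_season(
                weather_by_unit[s.unit_id], params, onoff=label,
                unit_id=s.unit_id, season=int(year))
    varieties = pd.DataFrame([
        {"unit_id": u.unit_id, "variety_1": u.varieties[0],
         "variety_2": u.varieties[1], "variety_3": u.varieties[2]}
        for u in config.units])
    official = labels_df[["unit_id", "year", "yield_t_ha"]]
    table = assemble_features(varieties, labels_df[["unit_id", "year",
                                                    "label"]],
                              sims, weather_by_unit, official)
    return {"config": config, "series": series, "summaries": summaries,
            "labels": labels_df, "sims": sims,
            "weather_by_unit": weather_by_unit, "table": table,
            "coeffs": coeffs}


@pytest.fixture(scope="session")
def default_bundle():
    return build_bundle(default_config(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def season_weather():
    """One deterministic unit × season of synthetic weather."""
    return gen_weather(default_config(seed=7), "sakarya", 2010)


@pytest.fixture(scope="session")
def on_off_sims(season_weather):
    """Paired on/off season runs under identical weather, coeff < 1."""
    params = HazelParams(offyear_coeff=0.6)
    on = simulate_season(season_weather, params, onoff="on", season=2010)
    off = simulate_season(season_weather, params, onoff="off", season=2010)
    return on, off
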