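"""Simulator components: radiation, chilling, phenology, canopy,
assimilation, partitioning, frost, the season loop, calibration and the
stratified hold-out."""

import numpy as np
import pandas as pd
import pytest

from hades.hazel_sim import (
    ORGANS, TRACKS, HazelParams, _SimState, calibrate, chilling_hours,
    daily_net_assimilation, degree_days, estimate_radiation,
    extraterrestrial_radiation, frost_damage, holdout_split,
    intercepted_radiation, partition_and_grow, phenology_mae, run_phenology,
    simulate_season,
)
from hades.synthetic_data import default_config, gen_weather


def constant_weather(tmin, tmax, season=2010, rh=60.0, rad=None):
    dates = pd.date_range(pd.Timestamp(season - 1, 9, 1),
                          pd.Timestamp(season, 8, 31), freq="D")
    w = pd.DataFrame({"date": dates, "tmin": tmin, "tmax": tmax,
                      "precip": 0.0, "rh": rh, "wind": 5.0})
    if rad is not None:
        w["rad"] = rad
    return w


class TestRadiation:
    def test_latitude_validation(self):
        w = constant_weather(5, 15)
        with pytest.raises(ValueError):
            estimate_radiation(w, 95.0)

    def test_zero_range_gives_overcast_minimum(self):
        w = constant_weather(10, 10)
        rad = estimate_radiation(w, 41.0)
        ra = extraterrestrial_radiation(
            pd.to_datetime(w["date"]).dt.dayofyear.to_numpy(), 41.0)
        assert np.allclose(rad, 0.10 * ra)

    def test_monotone_in_diurnal_range(self):
        lo = estimate_radiation(constant_weather(8, 12), 41.0)
        hi = estimate_radiation(constant_weather(4, 16), 41.0)
        assert np.all(hi > lo)

    def test_equator_equinox_near_clear_sky(self):
        # DOY 80 at the equator with a wide diurnal range: within 10% of
        # the clear-sky fraction of extraterrestrial radiation
        w = constant_weather(10, 30)
        dates = pd.to_datetime(w["date"])
        i = int(np.flatnonzero(dates.dt.dayofyear == 80)[0])
        rad = estimate_radiation(w, 0.0)
        ra = extraterrestrial_radiation(np.array([80.0]), 0.0)[0]
        assert rad[i] <= 0.75 * ra
        assert rad[i] >= 0.9 * 0.75 * ra


class TestChillingAndForcing:
    @pytest.mark.parametrize("tmin,tmax,expected", [
        (5.0, 5.0, 24.0),    # constant inside the window
        (10.0, 10.0, 0.0),   # constant outside
        (3.0, 11.0, 12.0),   # sinusoid with midpoint at the upper bound
        (0.0, 7.0, 24.0),    # whole swing inside
    ])
    def test_closed_forms(self, tmin, tmax, expected):
        assert chilling_hours(tmin, tmax) == pytest.approx(expected)

    @pytest.mark.parametrize("tmin,tmax", [(-5.0, 9.0), (6.0, 20.0),
                                           (-2.0, 4.0)])
    def test_matches_numeric_integration(self, tmin, tmax):
        h = np.linspace(0, 24, 200_000, endpoint=False)
        t = (tmin + tmax) / 2 + (tmax - tmin) / 2 * np.sin(2 * np.pi * h / 24)
        numeric = 24.0 * np.mean((t >= 0) & (t <= 7))
        assert chilling_hours(tmin, tmax) == pytest.approx(numeric, abs=2e-3)

    def test_degree_days(self):
        assert degree_days(4, 16, 5) == 5.0
        assert degree_days(0, 6, 5) == 0.0
        assert degree_days(4, 16, 0) == 10.0


class TestPhenology:
    def test_closed_form_onsets_without_chilling(self):
        # chilling_req = 0 and constant mean t_base + 10: stage k onset on
        # day ceil(threshold_k / 10)
        p = HazelParams(chilling_req=0.0)
        w = constant_weather(p.t_base + 5, p.t_base + 15, season=2010)
        onsets = run_phenology(w, p, season=2010)
        start = pd.Timestamp(2009, 9, 1)
        for track, thresholds in p.forcing_thresholds.items():
            for code, thr in zip(TRACKS[track], thresholds):
                day = int(np.ceil(thr / 10.0))
                assert onsets[track][code] == start + pd.Timedelta(
                    days=day - 1), (track, code)

    def test_identical_thresholds_identical_onsets(self):
        p = HazelParams(chilling_req=0.0)
        p.forcing_thresholds["C"] = p.forcing_thresholds["R"][:4].copy()
        w = constant_weather(10, 20, season=2010)
        onsets = run_phenology(w, p, season=2010)
        for i, code in enumerate(TRACKS["C"]):
            assert onsets["C"][code] == onsets["R"][TRACKS["R"][i]]

    def test_cold_season_never_forces(self):
        # constant 5 deg C: chilling completes but the mean never exceeds
        # t_base, so no stage is ever reached
        p = HazelParams(chilling_req=48.0, t_base=5.0)
        w = constant_weather(5.0, 5.0, season=2010)
        onsets = run_phenology(w, p, season=2010)
        assert all(len(v) == 0 for v in onsets.values())

    def test_onsets_strictly_increase_within_track(self, on_off_sims):
        sim, _ = on_off_sims
        for track, onsets in sim.stage_onsets.items():
            dates = [onsets[c] for c in TRACKS[track] if c in onsets]
            assert all(a < b for a, b in zip(dates, dates[1:]))


class TestCanopyAndAssimilation:
    def test_interception_limits(self):
        p = HazelParams()
        assert intercepted_radiation(0.0, 20.0, 0.5, p) == 0.0
        full = HazelParams(crown_size=4.0)   # crown area exceeds spacing
        assert intercepted_radiation(50.0, 20.0, 0.5, full) \
            == pytest.approx(20.0, rel=1e-6)
        assert intercepted_radiation(3.0, 20.0, 0.5, p) < 20.0
        with pytest.raises(ValueError):
            intercepted_radiation(-1.0, 20.0, 0.5, p)

    def test_interception_linear_in_cover(self):
        p1 = HazelParams(row_spacing=5.0, plant_spacing=2.0, crown_size=2.0)
        p2 = HazelParams(row_spacing=5.0, plant_spacing=4.0, crown_size=2.0)
        f1, f2 = 4.0 / 10.0, 4.0 / 20.0
        # same local LAI in both canopies
        lai_local = 3.0
        i1 = intercepted_radiation(lai_local * f1, 20.0, 0.5, p1)
        i2 = intercepted_radiation(lai_local * f2, 20.0, 0.5, p2)
        assert i1 == pytest.approx(2 * i2, rel=1e-12)

    def test_net_assimilation_zero_and_vpd_monotone(self):
        p = HazelParams()
        zero_biomass = {o: 0.0 for o in ORGANS}
        assert daily_net_assimilation(0.0, 20.0, 1.0, zero_biomass, p) == 0.0
        lo = daily_net_assimilation(10.0, 22.0, 0.5, zero_biomass, p)
        hi = daily_net_assimilation(10.0, 22.0, 1.0, zero_biomass, p)
        assert hi <= lo

    def test_gross_reaches_amax_at_optimum(self):
        p = HazelParams()
        zero_biomass = {o: 0.0 for o in ORGANS}
        net = daily_net_assimilation(1e6, p.t_opt, 0.0, zero_biomass, p)
        assert net == pytest.approx(p.amax * (1 - p.growth_resp_frac),
                                    rel=1e-9)


class TestPartitioning:
    def make_state(self, r_stage_idx, biomass=None):
        st = _SimState()
        st.stage_idx["R"] = r_stage_idx
        if biomass:
            st.biomass.update(biomass)
        return st

    def test_no_fruit_before_ovary_development(self):
        p = HazelParams()
        st = self.make_state(7)   # R7: before R10
        inc = partition_and_grow(st, 0.01, "on", p)
        assert inc["fruits"] == 0.0
        assert sum(inc.values()) == pytest.approx(0.01, rel=1e-12)

    def test_offyear_fruit_share(self):
        p = HazelParams(offyear_coeff=0.6)
        p.partition_table["R10"] = dict(leaves=0.2, fruits=0.5, stem=0.1,
                                        branches=0.1, roots=0.1)
        st = self.make_state(10)
        inc = partition_and_grow(st, 0.01, "off", p)
        assert inc["fruits"] == pytest.approx(0.003, rel=1e-12)
        assert sum(inc.values()) == pytest.approx(0.01, rel=1e-12)

    def test_coeff_one_is_noop(self):
        p = HazelParams(offyear_coeff=1.0)
        inc_on = partition_and_grow(self.make_state(11), 0.01, "on", p)
        inc_off = partition_and_grow(self.make_state(11), 0.01, "off", p)
        assert inc_on == inc_off

    def test_negative_assimilate_drawn_proportionally_and_floored(self):
        p = HazelParams()
        st = self.make_state(11, {"leaves": 0.02, "stem": 0.06,
                                  "branches": 0.0, "roots": 0.02,
                                  "fruits": 0.0})
        inc = partition_and_grow(st, -0.05, "on", p)
        assert sum(inc.values()) == pytest.approx(-0.05, rel=1e-12)
        assert inc["stem"] == pytest.approx(-0.03, rel=1e-12)
        assert all(v >= 0 for v in st.biomass.values())
        # drawing more than the total is floored at the total
        st2 = self.make_state(11, {"leaves": 0.01})
        inc2 = partition_and_grow(st2, -5.0, "on", p)
        assert sum(inc2.values()) == pytest.approx(-0.01, rel=1e-12)

    def test_lai_follows_leaf_increment(self):
        p = HazelParams()
        st = self.make_state(8)
        lai0 = st.lai
        inc = partition_and_grow(st, 0.01, "on", p)
        assert st.lai == pytest.approx(lai0 + p.sla * inc["leaves"])


class TestFrost:
    def test_damage_rules(self):
        p = HazelParams()
        peak = TRACKS["R"].index(p.frost_window_end) + 1
        before = TRACKS["R"].index(p.frost_window_start)  # pre-window
        assert frost_damage(2.0, peak, p) == 0.0            # mild night
        assert frost_damage(-10.0, peak, p) == 1.0          # full kill at peak
        assert frost_damage(-10.0, before, p) == 0.0        # outside window
        assert frost_damage(-10.0, peak + 1, p) == 0.0      # after the window
        mid = frost_damage(-4.0, peak, p)                   # partial severity
        assert 0.0 < mid < 1.0


class TestSeasonLoop:
    def test_zero_radiation_gives_zero_yield(self):
        p = HazelParams(chilling_req=0.0)
        w = constant_weather(10, 20, rad=0.0)
        sim = simulate_season(w, p, onoff="on", season=2010)
        assert sim.final_yield == 0.0

    def test_off_below_on_under_identical_weather(self, on_off_sims):
        on, off = on_off_sims
        assert off.final_yield < on.final_yield

    def test_daily_conservation(self, on_off_sims):
        sim, _ = on_off_sims
        d = sim.daily
        total = d[[f"biomass_{o}" for o in ORGANS]].sum(axis=1)
        inc = total.diff().dropna().to_numpy()
        net = d["net_assim"].to_numpy()[1:]
        assert np.allclose(inc, net, rtol=1e-9, atol=1e-15)

    def test_deterministic(self, season_weather):
        p = HazelParams()
        a = simulate_season(season_weather, p, onoff="on", season=2010)
        b = simulate_season(season_weather, p, onoff="on", season=2010)
        pd.testing.assert_frame_equal(a.daily, b.daily)
        assert a.final_yield == b.final_yield

    def test_frost_injection_reduces_yield(self, season_weather):
        p = HazelParams()
        base = simulate_season(season_weather, p, onoff="on", season=2010)
        frost_day = base.stage_onsets["R"][p.frost_window_end] \
            + pd.Timedelta(days=2)
        w = season_weather.copy()
        w["rad"] = estimate_radiation(w, p.latitude)  # decouple rad from tmin
        i = int((pd.to_datetime(w["date"]) == frost_day).idxmax())
        w.loc[i, "tmin"] = -8.0
        ref = simulate_season(w.drop(columns=[]), p, onoff="on", season=2010)
        w2 = w.copy()
        w2.loc[i, "tmin"] = season_weather["tmin"].iloc[i]
        no_frost = simulate_season(w2, p, onoff="on", season=2010)
        assert ref.final_yield < no_frost.final_yield
        assert ref.survival < 1.0

    def test_weather_gap_reported(self, season_weather):
        w = season_weather.drop(index=100)
        with pytest.raises(ValueError, match="gap"):
            simulate_season(w, HazelParams(), onoff="on", season=2010)

    def test_fruit_yield_monotone_except_frost(self, on_off_sims):
        sim, _ = on_off_sims
        fy = sim.daily["fruit_yield"].to_numpy()
        surv = sim.daily["survival"].to_numpy()
        drops = np.flatnonzero(np.diff(fy) < -1e-12)
        assert all(surv[i + 1] < surv[i] for i in drops)


class TestCalibration:
    def test_collapsed_bounds_return_the_point(self):
        p = HazelParams()
        res = calibrate(lambda q: abs(q.t_base - 5.0), p, ["t_base"],
                        {"t_base": (4.0, 4.0)}, n_starts=3, seed=0)
        assert res.values[0] == 4.0

    def test_single_start_reproducible(self):
        p = HazelParams()
        b = {"t_base": (2.0, 8.0)}
        obj = lambda q: (q.t_base - 5.5) ** 2
        r1 = calibrate(obj, p, ["t_base"], b, n_starts=1, seed=3)
        r2 = calibrate(obj, p, ["t_base"], b, n_starts=1, seed=3)
        assert np.array_equal(r1.values, r2.values)
        assert r1.objective == r2.objective

    def test_phenology_self_recovery_one_parameter(self):
        cfg = default_config(seed=9)
        weather = {2018: gen_weather(cfg, "ordu", 2018)}
        truth = HazelParams()
        truth.set_path("forcing_thresholds.R.9", 330.0)
        onsets = run_phenology(weather[2018], truth, season=2018)
        obs = pd.DataFrame([{"season": 2018, "track": "R",
                             "stage_code": c, "date": d}
                            for c, d in onsets["R"].items()])
        res = calibrate(lambda q: phenology_mae(obs, weather, q),
                        HazelParams(), ["forcing_thresholds.R.9"],
                        {"forcing_thresholds.R.9": (250.0, 420.0)},
                        n_starts=5, seed=1)
        assert res.objective <= 1.0


class TestHoldout:
    def grid(self, n_units=7, n_seasons=16):
        rows = []
        for u in range(n_units):
            for s in range(n_seasons):
                rows.append({"unit_id": f"u{u}", "season": 2004 + s,
                             "onoff": "on" if s % 2 == 0 else "off"})
        return pd.DataFrame(rows)

    def test_balanced_grid_splits_exactly(self):
        records = self.grid()
        cal, ev = holdout_split(records, seed=5)
        assert len(cal) == len(ev) == 56
        for part in (cal, ev):
            counts = part.groupby(["unit_id", "onoff"]).size()
            assert (counts == 4).all()

    def test_strata_differ_by_at_most_one(self):
        records = self.grid(n_units=3, n_seasons=5)
        cal, ev = holdout_split(records, seed=2)
        c1 = cal.groupby(["unit_id", "onoff"]).size()
        c2 = ev.groupby(["unit_id", "onoff"]).size()
        diff = (c1.subtract(c2, fill_value=0)).abs()
        assert (diff <= 1).all()

    def test_singleton_stratum_goes_to_calibration(self):
        records = pd.DataFrame([
            {"unit_id": "a", "onoff": "on"},
            {"unit_id": "a", "onoff": "off"},
            {"unit_id": "a", "onoff": "off"},
        ])
        with pytest.warns(UserWarning, match="size 1"):
            cal, ev = holdout_split(records, seed=0)
        assert ((cal["onoff"] == "on").sum(), (ev["onoff"] == "on").sum()) \
            == (1, 0)
        assert (cal["onoff"] == "off").sum() == (ev["onoff"] == "off").sum() == 1
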