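import math

import numpy as np
import pytest

from fawtrack.synth import WindSimConfig, simulate_wind_field
from fawtrack.trajectory import (
    EARTH_RADIUS_M,
    FlightParams,
    Trajectory,
    batch_simulate,
    landing_frequency,
    multi_generation_relaunch,
    simulate_trajectory,
    step_position,
)
from fawtrack.wind import OutsideGridError, WindField

DEG_M = EARTH_RADIUS_M * math.pi / 180.0   # metres per degree of latitude


class TestWindInterpolation:
    def test_grid_node_query_is_exact(self, uniform_field):
        f = uniform_field
        u, v = f.interpolate_wind(f.times[2], f.lons[3], f.lats[1], f.levels[0])
        assert (u, v) == (10.0, 0.0)

    def test_time_midpoint_linearity(self):
        cfg = WindSimConfig(regime="uniform", u0=0.0, v0=0.0,
                            time_start="2018-06-01T00:00",
                            time_end="2018-06-01T12:00", d_t_hours=6.0)
        f = simulate_wind_field(cfg)
        f.u[1] = 4.0  # step function in time: 0, 4, ...
        f._build_interpolators()
        u, _ = f.interpolate_wind(np.datetime64("2018-06-01T03:00"), 0, 0, 1000)
        assert u == pytest.approx(2.0)

    def test_outside_grid_raises(self, uniform_field):
        with pytest.raises(OutsideGridError):
            uniform_field.interpolate_wind(uniform_field.times[0], 100.0, 0.0, 1000.0)


class TestStepPosition:
    def test_downwind_displacement_arithmetic(self):
        # wind (10,0) + 3 m/s airspeed for 1 h at the equator: 46.8 km east
        lon, lat = step_position(0.0, 0.0, 10.0, 0.0, 3.0, 3600.0)
        assert lat == 0.0
        assert lon * DEG_M == pytest.approx(46_800.0)

    def test_calm_air_rule_zero_displacement(self):
        assert step_position(5.0, 5.0, 0.0, 0.0, 3.0, 3600.0) == (5.0, 5.0)

    def test_meridional_step_latitude_independent(self):
        _, dlat0 = step_position(0.0, 0.0, 0.0, 10.0, 0.0, 3600.0)
        _, dlat60 = step_position(0.0, 60.0, 0.0, 10.0, 0.0, 3600.0)
        assert dlat60 - 60.0 == pytest.approx(dlat0)

    def test_zonal_step_scales_with_cos_latitude(self):
        lon0, _ = step_position(0.0, 0.0, 10.0, 0.0, 0.0, 3600.0)
        lon60, _ = step_position(0.0, 60.0, 10.0, 0.0, 0.0, 3600.0)
        assert lon60 == pytest.approx(lon0 / math.cos(math.radians(60.0)))

    def test_polar_cap_rejected(self):
        with pytest.raises(ValueError):
            step_position(0.0, 89.5, 1.0, 0.0, 0.0, 60.0)


class TestSimulateTrajectory:
    def test_uniform_wind_full_night_closed_form(self, uniform_field):
        p = FlightParams(timestep_minutes=10.0)
        tr = simulate_trajectory(uniform_field, 0.0, 0.0, "2018-06-02", p, 1000.0)
        assert tr.outcome == "landed"
        assert tr.flight_duration_h == pytest.approx(10.0)
        # 13 m/s for 36,000 s = 468 km east
        expected_lon = 468_000.0 / DEG_M
        assert tr.landing[0] == pytest.approx(expected_lon, rel=1e-3)

    def test_timestep_halving_reduces_displacement_error(self):
        # slight meridional component makes the Euler error visible
        cfg = WindSimConfig(regime="uniform", u0=10.0, v0=3.0,
                            lon_min=-5, lon_max=15, lat_min=-5, lat_max=10,
                            continents=[(-5, 15, -5, 10)],
                            time_start="2018-06-01", time_end="2018-06-05")
        f = simulate_wind_field(cfg)
        speed = math.hypot(10.0, 3.0)
        scale = 1.0 + 3.0 / speed
        east_m = 10.0 * scale * 36_000.0
        north_m = 3.0 * scale * 36_000.0
        lat_exp = north_m / DEG_M
        errors = []
        for step in (20.0, 10.0, 5.0):
            tr = simulate_trajectory(
                f, 0.0, 0.0, "2018-06-02", FlightParams(timestep_minutes=step), 1000.0
            )
            # exact lon needs the lat-dependent metric; compare lat only
            errors.append(abs(tr.landing[1] - lat_exp))
        assert errors[0] >= errors[1] >= errors[2] or max(errors) < 1e-9

    def test_sea_strip_extension_lands_on_far_shore(self):
        km = 1.0 / (EARTH_RADIUS_M / 1000.0 * math.pi / 180.0)
        cfg = WindSimConfig(
            regime="uniform", u0=10.0, v0=0.0,
            lon_min=-5, lon_max=20, lat_min=-5, lat_max=5,
            d_lon=0.05,
            continents=[(-5, 100 * km, -5, 5), (700 * km, 20, -5, 5)],
            time_start="2018-06-01", time_end="2018-06-05",
        )
        f = simulate_wind_field(cfg)
        tr = simulate_trajectory(f, 0.0, 0.0, "2018-06-02",
                                 FlightParams(timestep_minutes=10.0), 1000.0)
        assert tr.outcome == "landed"
        assert tr.flight_duration_h > 10.0
        # far shore at 700 km; 468 km at 10 h, remainder at 13 m/s:
        # 10 h + 232 km / 13 m/s = 14.96 h, landing at the next step
        assert tr.flight_duration_h == pytest.approx(15.0, abs=0.2)
        assert f.is_land(*tr.landing[:2])

    def test_against_trade_wind_no_crossing(self):
        cfg = WindSimConfig(
            regime="trade_easterly", u0=10.0,
            lon_min=-25, lon_max=25, lat_min=-5, lat_max=5,
            continents=[(-25, -10, -5, 5), (10, 25, -5, 5)],
            time_start="2018-06-01", time_end="2018-06-08",
        )
        f = simulate_wind_field(cfg)
        tr = simulate_trajectory(f, -11.0, 0.0, "2018-06-02",
                                 FlightParams(timestep_minutes=10.0), 1000.0)
        # the wind blows away from the eastern continent: no crossing
        assert not (tr.outcome == "landed" and tr.landing[0] > 0.0)

    def test_launch_on_sea_rejected(self, uniform_field):
        field = uniform_field
        field.landmask[:] = False
        field_sea = WindField(
            times=field.times, levels=field.levels, lats=field.lats,
            lons=field.lons, u=field.u, v=field.v,
            landmask=np.zeros_like(field.landmask), terrain=field.terrain,
        )
        with pytest.raises(ValueError, match="not on land"):
            simulate_trajectory(field_sea, 0.0, 0.0, "2018-06-02",
                                FlightParams(), 1000.0)

    def test_reversed_wind_reverses_displacement(self):
        base = dict(lon_min=-15, lon_max=15, lat_min=-5, lat_max=5,
                    continents=[(-15, 15, -5, 5)],
                    time_start="2018-06-01", time_end="2018-06-05")
        p = FlightParams(timestep_minutes=10.0)
        f_e = simulate_wind_field(WindSimConfig(regime="uniform", u0=5.0, **base))
        f_w = simulate_wind_field(WindSimConfig(regime="uniform", u0=-5.0, **base))
        tr_e = simulate_trajectory(f_e, 0.0, 0.0, "2018-06-02", p, 1000.0)
        tr_w = simulate_trajectory(f_w, 0.0, 0.0, "2018-06-02", p, 1000.0)
        assert tr_e.landing[0] == pytest.approx(-tr_w.landing[0])

    def test_rotational_field_closed_orbit(self):
        cfg = WindSimConfig(regime="rotational", u0=10.0,
                            lon_min=-10, lon_max=10, lat_min=-10, lat_max=10,
                            time_start="2018-06-01", time_end="2018-06-12")
        f = simulate_wind_field(cfg)
        omega = 10.0 / 1e6
        period_s = 2.0 * math.pi / omega
        dt = 60.0
        lon, lat = 2.0, 0.0
        t = np.datetime64("2018-06-02T00:00", "s")
        for _ in range(int(round(period_s / dt))):
            u, v = f.interpolate_wind(t, lon, lat, 1000.0)
            lon, lat = step_position(lon, lat, u, v, 0.0, dt)
            t += np.timedelta64(60, "s")
        assert math.hypot(lon - 2.0, lat) < 0.02 * 2.0


class TestBatchAndAggregation:
    def test_cartesian_product_counts(self, uniform_field):
        p = FlightParams(timestep_minutes=10.0)
        sites = [(0.0, 0.0), (1.0, 1.0), (2.0, -1.0)]
        trajs, summary = batch_simulate(uniform_field, sites, ["2018-06-02"],
                                        p, altitudes=(500.0, 1000.0))
        assert len(trajs) == 6
        assert summary.iloc[0]["landed"] == 6

    def test_all_land_uniform_durations_degenerate(self, uniform_field):
        p = FlightParams(timestep_minutes=10.0)
        trajs, summary = batch_simulate(uniform_field, [(0.0, 0.0)],
                                        ["2018-06-02"], p, altitudes=(1000.0,))
        row = summary.iloc[0]
        assert row["mean_duration_h"] == row["min_duration_h"] == row["max_duration_h"] == 10.0

    def test_summary_matches_direct_recomputation(self, uniform_field):
        p = FlightParams(timestep_minutes=10.0)
        trajs, summary = batch_simulate(
            uniform_field, [(0.0, 0.0), (3.0, 2.0)], ["2018-06-02"], p,
            altitudes=(500.0, 1500.0),
        )
        durations = [t.flight_duration_h for t in trajs if t.outcome == "landed"]
        assert summary.iloc[0]["mean_duration_h"] == pytest.approx(np.mean(durations))
        assert summary.iloc[0]["min_duration_h"] == pytest.approx(np.min(durations))

    def test_no_landed_trajectory_on_sea(self):
        km = 1.0 / (EARTH_RADIUS_M / 1000.0 * math.pi / 180.0)
        cfg = WindSimConfig(
            regime="uniform", u0=10.0, v0=1.0,
            lon_min=-5, lon_max=20, lat_min=-5, lat_max=5, d_lon=0.1,
            continents=[(-5, 2, -5, 5), (8, 20, -5, 5)],
            time_start="2018-06-01", time_end="2018-06-06",
        )
        f = simulate_wind_field(cfg)
        trajs, _ = batch_simulate(f, [(0.0, 0.0), (1.0, 1.0)],
                                  ["2018-06-02", "2018-06-03"],
                                  FlightParams(timestep_minutes=10.0),
                                  altitudes=(500.0, 1000.0))
        for tr in trajs:
            if tr.outcome == "landed":
                assert f.is_land(tr.landing[0], tr.landing[1])

    def test_duration_exceeds_ten_hours_only_for_post_stop_landings(self):
        km = 1.0 / (EARTH_RADIUS_M / 1000.0 * math.pi / 180.0)
        cfg = WindSimConfig(
            regime="uniform", u0=10.0, v0=0.0,
            lon_min=-5, lon_max=20, lat_min=-5, lat_max=5, d_lon=0.05,
            continents=[(-5, 100 * km, -5, 5), (700 * km, 20, -5, 5)],
            time_start="2018-06-01", time_end="2018-06-06",
        )
        f = simulate_wind_field(cfg)
        p = FlightParams(timestep_minutes=10.0)
        over_sea = simulate_trajectory(f, 0.0, 0.0, "2018-06-02", p, 1000.0)
        on_land = simulate_trajectory(f, -4.0, 0.0, "2018-06-02", p, 1000.0)
        assert over_sea.flight_duration_h > 10.0
        assert on_land.flight_duration_h == 10.0


class TestMultiGeneration:
    def test_generation_two_launches_displaced_downwind(self, uniform_field):
        p = FlightParams(timestep_minutes=10.0)
        gens = multi_generation_relaunch(
            uniform_field, [(0.0, 0.0)], ["2018-06-02"], p,
            n_generations=2, dwell_nights=1, altitudes=(1000.0,), cell_size=1.0,
        )
        assert len(gens) == 2
        g2_lon = gens[1]["sites"][0][0]
        assert g2_lon == pytest.approx(4.5, abs=1.0)   # ~468 km + cell centre

    def test_single_generation_equals_batch(self, uniform_field):
        p = FlightParams(timestep_minutes=10.0)
        gens = multi_generation_relaunch(
            uniform_field, [(0.0, 0.0)], ["2018-06-02"], p,
            n_generations=1, altitudes=(1000.0,),
        )
        trajs, _ = batch_simulate(uniform_field, [(0.0, 0.0)], ["2018-06-02"],
                                  p, altitudes=(1000.0,))
        assert gens[0]["trajectories"][0].landing == trajs[0].landing

    def test_zero_wind_all_generations_land_at_origin(self):
        cfg = WindSimConfig(regime="uniform", u0=0.0, v0=0.0,
                            continents=[(-10, 10, -10, 10)],
                            time_start="2018-06-01", time_end="2018-08-01",
                            d_t_hours=24.0)
        f = simulate_wind_field(cfg)
        p = FlightParams(timestep_minutes=10.0)
        gens = multi_generation_relaunch(
            f, [(0.2, 0.2)], ["2018-06-02"], p, n_generations=3,
            dwell_nights=5, altitudes=(1000.0,), cell_size=1.0,
        )
        for g in gens:
            assert list(g["landing_grid"].counts) == [(0.0, 0.0)]


class TestLandingFrequency:
    def _traj(self, lon, lat, outcome="landed"):
        return Trajectory(
            launch_lon=0.0, launch_lat=0.0, launch_date="2018-06-02",
            altitude=1000.0, path=[], outcome=outcome,
            landing=(lon, lat, np.datetime64("2018-06-03T05:00")),
            flight_duration_h=10.0,
        )

    def test_single_cell_count_and_frequency(self):
        grid = landing_frequency([self._traj(3.2, 1.7)] * 10, cell_size=1.0)
        assert grid.counts == {(3.0, 1.0): 10}
        assert grid.frequencies()[(3.0, 1.0)] == 1.0

    def test_boundary_goes_to_higher_cell(self):
        grid = landing_frequency([self._traj(2.0, 1.0)], cell_size=1.0)
        assert grid.counts == {(2.0, 1.0): 1}

    def test_counts_conserve_landed_trajectories(self):
        trajs = [self._traj(0.5, 0.5), self._traj(5.5, 0.5),
                 self._traj(0.5, 0.5), self._traj(0.0, 0.0, "aloft_at_cap")]
        grid = landing_frequency(trajs, cell_size=1.0)
        assert grid.n_landed == 3
        assert sum(grid.frequencies().values()) == pytest.approx(1.0)

    def test_empty_input_empty_grid(self):
        grid = landing_frequency([], cell_size=2.0)
        assert grid.counts == {}
        assert grid.to_frame().empty
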