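"""Lagrangian downwind flight of a nocturnal insect migrant.

The behavioral model: the insect takes off at 19:00 local (solar) time,
flies strictly downwind with a self-powered airspeed added to the wind
speed, and stops at 05:00 local — unless it is over the sea, in which
case flight continues until the first land cell is crossed or an
endurance cap is exceeded. Altitude is constant per trajectory, either
a fixed height above sea level or terrain + a fixed height above
ground. Local time is solar time, UTC + longitude/15 hours: the
nightly window is photoperiod-driven, not a civil-timezone matter.

Positions advance by first-order (Euler) steps on a sphere of radius
6,371,000 m; below a 0.1 m/s wind-speed floor the downwind heading is
undefined and the airspeed term is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fawtrack.wind import OutsideGridError, WindField

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0
DEG = np.pi / 180.0
CALM_WIND_MS = 0.1          # below this, no defined downwind heading
NIGHT_HOURS = 10.0          # 19:00 -> 05:00 local


@dataclass
class FlightParams:
    """Behavioral and numerical parameters of a flight night."""

    airspeed: float = 3.0                 # m/s, added along the wind vector
    launch_local_time: float = 19.0       # hours, solar time
    stop_local_time: float = 5.0          # next day
    altitudes_asl: tuple[float, ...] = (
        500.0, 750.0, 1000.0, 1250.0, 1500.0, 1750.0, 2000.0, 2250.0,
    )
    altitude_agl: float | None = None     # terrain-following height (m a.g.l.)
    timestep_minutes: float = 10.0
    max_extension_hours: float = 96.0     # over-sea endurance cap past 05:00

    def __post_init__(self) -> None:
        if self.airspeed < 0:
            raise ValueError("airspeed must be >= 0")
        if self.max_extension_hours < 0:
            raise ValueError("max_extension_hours must be >= 0")
        steps = NIGHT_HOURS * 60.0 / self.timestep_minutes
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("timestep must divide the 10-hour night window")


@dataclass
class Trajectory:
    launch_lon: float
    launch_lat: float
    launch_date: str              # local calendar date of the 19:00 departure
    altitude: float               # m a.s.l., or a.g.l. target in agl mode
    path: list[tuple]             # (UTC datetime64, lon, lat, alt, over_sea)
    outcome: str                  # landed | aloft_at_cap | exited_grid
    landing: tuple | None = None  # (lon, lat, UTC time)
    flight_duration_h: float | None = None


@dataclass
class LandingGrid:
    cell_size: float
    counts: dict[tuple[float, float], int] = field(default_factory=dict)

    @property
    def n_landed(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[tuple[float, float], float]:
        total = self.n_landed
        if total == 0:
            return {}
        return {cell: n / total for cell, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies()
        rows = [
            {"lon": c[0], "lat": c[1], "count": n, "frequency": freq[c]}
            for c, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["lon", "lat", "count", "frequency"])


def interpolate_wind(field: WindField, t, lon, lat, alt):
    """Wind (u, v) at a point; see :meth:`WindField.interpolate_wind`."""
    return field.interpolate_wind(t, lon, lat, alt)


def step_position(
    lon: float, lat: float, u: float, v: float, airspeed: float, dt: float
) -> tuple[float, float]:
    """One Euler step: ground velocity = wind + airspeed along the wind
    unit vector, converted to degrees on the sphere. ``dt`` in seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if abs(lat) >= 89.0:
        raise ValueError("position in polar cap, outside biological range")
    speed = np.hypot(u, v)
    if speed < CALM_WIND_MS:
        ug, vg = u, v
    else:
        scale = 1.0 + airspeed / speed
        ug, vg = u * scale, v * scale
    dlat = vg * dt / EARTH_RADIUS_M / DEG
    dlon = ug * dt / (EARTH_RADIUS_M * np.cos(lat * DEG)) / DEG
    lon2 = lon + dlon
    if lon2 > 180.0:
        lon2 -= 360.0
    elif lon2 <= -180.0:
        lon2 += 360.0
    return lon2, lat + dlat


def _launch_utc(local_date: str, lon: float, launch_local_time: float) -> np.datetime64:
    base = np.datetime64(f"{local_date}T00:00", "s")
    offset_h = launch_local_time - lon / 15.0
    return base + np.timedelta64(int(round(offset_h * 3600)), "s")


def simulate_trajectory(
    field: WindField,
    lon: float,
    lat: float,
    local_date: str,
    params: FlightParams,
    altitude: float,
) -> Trajectory:
    """Integrate one flight night (plus any over-sea extension).

    ``altitude`` is the m-a.s.l. flight level, or the a.g.l. height when
    ``params.altitude_agl`` is set (then terrain + that height is used
    and ``altitude`` is ignored). Landing at 05:00 local requires a
    land cell; otherwise flight continues and lands at the first land
    cell crossed, or ends ``aloft_at_cap`` when the endurance cap is
    exceeded. Leaving the grid ends the trajectory with
    ``exited_grid``.
    """
    if not field.is_land(lon, lat):
        raise ValueError(f"launch site ({lon}, {lat}) is not on land")
    launch_lon, launch_lat = lon, lat
    t = _launch_utc(local_date, lon, params.launch_local_time)
    if not field.in_time_bounds(t):
        raise ValueError("wind field does not cover the launch time")
    dt_s = params.timestep_minutes * 60.0
    night_s = NIGHT_HOURS * 3600.0
    cap_s = night_s + params.max_extension_hours * 3600.0

    agl = params.altitude_agl
    alt = field.terrain_at(lon, lat) + agl if agl is not None else altitude
    path = [(t, lon, lat, alt, not field.is_land(lon, lat))]
    elapsed = 0.0
    outcome = "aloft_at_cap"
    landing = None
    duration = None

    while elapsed < cap_s - 1e-9:
        try:
            u, v = field.interpolate_wind(t, lon, lat, alt)
            lon, lat = step_position(lon, lat, u, v, params.airspeed, dt_s)
        except OutsideGridError:
            outcome = "exited_grid"
            break
        t = t + np.timedelta64(int(dt_s), "s")
        elapsed += dt_s
        if not field.in_horizontal_bounds(lon, lat) or not field.in_time_bounds(t):
            outcome = "exited_grid"
            break
        on_land = field.is_land(lon, lat)
        if agl is not None:
            alt = field.terrain_at(lon, lat) + agl
        path.append((t, lon, lat, alt, not on_land))
        if elapsed >= night_s - 1e-9 and on_land:
            # at/after the 05:00 local stop and over land: land now
            outcome = "landed"
            landing = (lon, lat, t)
            duration = elapsed / 3600.0
            break

    return Trajectory(
        launch_lon=launch_lon,
        launch_lat=launch_lat,
        launch_date=local_date,
        altitude=altitude if agl is None else agl,
        path=path,
        outcome=outcome,
        landing=landing,
        flight_duration_h=duration,
    )


def batch_simulate(
    field: WindField,
    sites: list[tuple[float, float]],
    dates: list[str],
    params: FlightParams,
    altitudes: tuple[float, ...] | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Cartesian product of sites × nightly launches × altitudes.

    Per-trajectory errors (e.g. a site off land) are recorded as failed
    attempts, not raised. Returns trajectories plus a per-night summary
    of outcome counts and landed-duration statistics.
    """
    if not sites or not dates:
        raise ValueError("need at least one site and one date")
    if params.altitude_agl is not None:
        altitudes = (params.altitude_agl,)
    elif altitudes is None:
        altitudes = params.altitudes_asl
    trajs: list[Trajectory] = []
    rows = []
    for date in dates:
        outcomes = {"landed": 0, "aloft_at_cap": 0, "exited_grid": 0, "failed": 0}
        durations = []
        for lon, lat in sites:
            for alt in altitudes:
                try:
                    tr = simulate_trajectory(field, lon, lat, date, params, alt)
                except (ValueError, OutsideGridError) as exc:
                    log.warning("launch (%s, %s) on %s failed: %s", lon, lat, date, exc)
                    outcomes["failed"] += 1
                    continue
                trajs.append(tr)
                outcomes[tr.outcome] += 1
                if tr.outcome == "landed":
                    durations.append(tr.flight_duration_h)
        rows.append(
            {
                "date": date,
                **outcomes,
                "mean_duration_h": float(np.mean(durations)) if durations else np.nan,
                "min_duration_h": float(np.min(durations)) if durations else np.nan,
                "max_duration_h": float(np.max(durations)) if durations else np.nan,
            }
        )
    return trajs, pd.DataFrame(rows)


def multi_generation_relaunch(
    field: WindField,
    sites: list[tuple[float, float]],
    dates: list[str],
    params: FlightParams,
    n_generations: int,
    dwell_nights: int = 30,
    altitudes: tuple[float, ...] | None = None,
    cell_size: float = 1.0,
) -> list[dict]:
    """Chain generations: each generation launches from the previous
    generation's landing cells after ``dwell_nights`` nights.

    Returns one record per generation with its trajectories, landing
    grid, and launch sites. A generation with zero landings ends the
    chain early (logged)."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    out = []
    cur_sites = list(sites)
    cur_dates = list(dates)
    for gen in range(n_generations):
        trajs, summary = batch_simulate(field, cur_sites, cur_dates, params, altitudes)
        grid = landing_frequency(trajs, cell_size)
        out.append(
            {"generation": gen + 1, "trajectories": trajs,
             "landing_grid": grid, "summary": summary, "sites": cur_sites}
        )
        landed = [t for t in trajs if t.outcome == "landed"]
        if not landed:
            log.info("generation %d produced no landings; chain stopped", gen + 1)
            break
        # next generation launches from the centre of each landing cell
        cur_sites = [
            (c[0] + cell_size / 2.0, c[1] + cell_size / 2.0)
            for c in grid.counts
        ]
        shift = np.timedelta64(dwell_nights, "D")
        cur_dates = [
            str((np.datetime64(d) + shift).astype("datetime64[D]")) for d in cur_dates
        ]
    return out


def landing_frequency(trajectories: list[Trajectory], cell_size: float) -> LandingGrid:
    """Bin landing points into half-open cells keyed by their lower-left
    corner; a landing on a boundary goes to the higher cell."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    grid = LandingGrid(cell_size=cell_size)
    for tr in trajectories:
        if tr.outcome != "landed":
            continue
        lon, lat, _ = tr.landing
        cell = (
            np.floor(lon / cell_size) * cell_size,
            np.floor(lat / cell_size) * cell_size,
        )
        cell = (float(cell[0]), float(cell[1]))
        grid.counts[cell] = grid.counts.get(cell, 0) + 1
    return grid


def trajectories_to_geojson(trajectories: list[Trajectory]) -> dict:
    """GeoJSON FeatureCollection of LineString paths with launch/outcome
    metadata."""
    feats = []
    for tr in trajectories:
        coords = [[float(lon), float(lat)] for _, lon, lat, _, _ in tr.path]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "launch_lon": tr.launch_lon,
                    "launch_lat": tr.launch_lat,
                    "date": tr.launch_date,
                    "altitude_m": tr.altitude,
                    "outcome": tr.outcome,
                    "duration_h": tr.flight_duration_h,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
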