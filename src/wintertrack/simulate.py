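"""Simulation of dispersive winter migration and its tag observables.

Birds leave their colony after moult, perform a habitat-biased correlated
random walk over the winter at twice-daily resolution, and return to the
colony in spring.  Step speeds follow a zero-truncated normal whose
*post-truncation* mean and SD equal the movement model's nominal 3 and
1.8 km/h; headings are chosen by multinomial (softmax) choice over
candidate bearings scored by habitat preference, persistence and — late in
the trip — homing.  Land and >10% sea-ice cells are never entered.

From each true track the module produces the two tag observables the rest
of the pipeline consumes: noisy dawn/dusk twilight times (for geolocation)
and daily wet/dry immersion fractions (for phenology).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import solar
from .environment import HabitatStack, ColonySpec
from .grids import haversine_km, initial_bearing_rad, displace


class SimulationError(RuntimeError):
    pass


def truncnorm_at_zero(mean: float, sd: float):
    """Frozen zero-truncated normal whose truncated moments are (mean, sd).

    The underlying (pre-truncation) location/scale are solved numerically
    so the distribution actually has the nominal mean and SD; with the
    naive parameterization truncation at zero would inflate the mean.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if sd >= 0.75 * mean:
        # a zero-truncated normal cannot reach sd/mean ratios much above
        # the half-normal's; fall back to truncating N(mean, sd) directly
        # (this is also the right weak-prior limit as sd grows)
        return stats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = -mu / sigma
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sigma)
        m, v = d.stats(moments="mv")
        return [float(m) - mean, np.sqrt(float(v)) - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-conditioned for mean>0
        raise RuntimeError("could not match truncated-normal moments")
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return stats.truncnorm(-mu / sigma, np.inf, loc=mu, scale=sigma)


@dataclass
class MovementModel:
    """Winter movement parameters.

    mean_speed/speed_sd (km/h) describe the speed distribution used both to
    simulate steps and as the smoothing prior in geolocation.  The same
    numbers give the speed-feasibility bound for intermediate-location
    clouds (``max_speed`` = mean + 4 SD by default).
    """

    mean_speed: float = 3.0
    speed_sd: float = 1.8
    habitat_preference: dict = field(default_factory=dict)
    turning_concentration: float = 1.0

    def __post_init__(self):
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        if self.speed_sd < 0:
            raise ValueError("speed_sd must be non-negative")
        self._speed_dist = None

    @property
    def speed_dist(self):
        if self._speed_dist is None:
            self._speed_dist = truncnorm_at_zero(self.mean_speed, max(self.speed_sd, 1e-9))
        return self._speed_dist

    @property
    def max_speed(self) -> float:
        return self.mean_speed + 4.0 * self.speed_sd


@dataclass
class TrueTrack:
    """Ground-truth simulated track at twice-daily resolution."""

    bird_id: str
    colony: str
    sex: str
    times: pd.DatetimeIndex
    lons: np.ndarray
    lats: np.ndarray
    departure: pd.Timestamp
    return_date: pd.Timestamp

    def __len__(self):
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bird_id": self.bird_id, "colony": self.colony,
                             "sex": self.sex, "time": self.times,
                             "lon": self.lons, "lat": self.lats})

    def speeds_kmh(self) -> np.ndarray:
        d = haversine_km(self.lons[:-1], self.lats[:-1], self.lons[1:], self.lats[1:])
        dt = np.diff(self.times.view("int64")) / 3.6e12
        return d / dt


def launch_point(colony: ColonySpec, habitat: HabitatStack) -> tuple[float, float]:
    """Nearest ocean cell-center to the colony (tracks start/end there).

    Colonies sit on land cells; birds are simulated from the adjacent sea.
    """
    grid = habitat.grid
    ilat, ilon, inside = grid.index(colony.lon, colony.lat)
    if not inside:
        raise SimulationError(f"colony {colony.name} outside habitat extent")
    ocean = habitat.ocean
    for radius in (1, 2, 3):
        best, best_d = None, np.inf
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                i, j = int(ilat) + di, int(ilon) + dj
                if 0 <= i < grid.nlat and 0 <= j < grid.nlon and ocean[i, j]:
                    lon_c = grid.lon_centers[j]
                    lat_c = grid.lat_centers[i]
                    d = haversine_km(colony.lon, colony.lat, lon_c, lat_c)
                    if d < best_d:
                        best, best_d = (lon_c, lat_c), d
        if best is not None:
            return best
    raise SimulationError(f"colony {colony.name} is surrounded by land/ice")


N_CANDIDATE_HEADINGS = 24


def _escape(lon, lat, habitat: HabitatStack, month: int, dist_km: float):
    """Move toward the nearest unblocked cell center (used when engulfed)."""
    grid = habitat.grid
    open_cells = habitat.ocean & ~habitat.ice(month)
    lon2d, lat2d = grid.center_mesh()
    d = haversine_km(lon, lat, lon2d[open_cells], lat2d[open_cells])
    k = int(np.argmin(d))
    tgt_lon = lon2d[open_cells][k]
    tgt_lat = lat2d[open_cells][k]
    if d[k] <= dist_km:
        return float(tgt_lon), float(tgt_lat)
    b = initial_bearing_rad(lon, lat, tgt_lon, tgt_lat)
    new_lon, new_lat = displace(lon, lat, b, dist_km)
    if habitat.is_blocked(new_lon, new_lat, month):
        return float(tgt_lon), float(tgt_lat)  # jump clear rather than linger
    return float(new_lon), float(new_lat)


def _simulate_one(bird_id, colony, sex, habitat, model, start, end, step_hours, rng):
    times = pd.date_range(start, end, freq=f"{step_hours}h")
    n_steps = len(times) - 1
    lon0, lat0 = launch_point(colony, habitat)
    lons = np.empty(len(times))
    lats = np.empty(len(times))
    lons[0], lats[0] = lon0, lat0

    pref = model.habitat_preference or {}
    pref_layers = [(habitat.standardized(k), w) for k, w in pref.items() if w != 0.0]
    kappa = model.turning_concentration
    theta_prev = rng.uniform(-np.pi, np.pi)
    base_angles = np.linspace(-np.pi, np.pi, N_CANDIDATE_HEADINGS, endpoint=False)
    grid = habitat.grid

    for t in range(n_steps):
        month = times[t + 1].month
        speed = float(model.speed_dist.rvs(random_state=rng))
        angles = base_angles + rng.uniform(0, 2 * np.pi / N_CANDIDATE_HEADINGS)
        # look ahead across month boundaries so birds vacate cells the
        # advancing monthly ice mask is about to cover
        months_ahead = [month]
        if (times[t + 1] + pd.Timedelta(days=4)).month != month:
            months_ahead.append((times[t + 1] + pd.Timedelta(days=4)).month)
        # near concave coast/ice all candidates can be blocked at the drawn
        # distance; shorten the step rather than freezing in place
        for factor in (1.0, 0.5, 0.25):
            dist = speed * step_hours * factor
            cand_lon, cand_lat = displace(lons[t], lats[t], angles, dist)
            blocked = np.zeros(len(angles), dtype=bool)
            for m in months_ahead:
                blocked |= habitat.is_blocked(cand_lon, cand_lat, m)
            if not blocked.all():
                break
        if blocked.all():
            # engulfed (e.g. ice advanced over the current cell): head
            # straight for the nearest open cell
            lons[t + 1], lats[t + 1] = _escape(lons[t], lats[t], habitat, month,
                                               speed * step_hours)
            theta_prev = float(initial_bearing_rad(lons[t], lats[t],
                                                   lons[t + 1], lats[t + 1]))
            continue

        score = kappa * np.cos(angles - theta_prev)
        if pref_layers:
            ilat, ilon, inside = grid.index(cand_lon, cand_lat)
            ilat = np.clip(ilat, 0, grid.nlat - 1)
            ilon = np.clip(ilon, 0, grid.nlon - 1)
            for layer, w in pref_layers:
                score = score + np.where(inside, w * layer[ilat, ilon], -5.0)

        # homing ramp: bias toward the colony when remaining time gets tight
        hours_left = (n_steps - t) * step_hours
        d_home = float(haversine_km(lons[t], lats[t], lon0, lat0))
        needed = d_home / model.mean_speed
        ratio = needed / max(hours_left, 1e-9)
        if ratio > 0.6:
            home_bearing = float(initial_bearing_rad(lons[t], lats[t], lon0, lat0))
            score = score + 12.0 * max(ratio - 0.6, 0.0) * np.cos(angles - home_bearing)

        score = np.where(blocked, -np.inf, score)
        p = np.exp(score - np.nanmax(score[np.isfinite(score)]))
        p[~np.isfinite(p)] = 0.0
        k = rng.choice(len(angles), p=p / p.sum())
        lons[t + 1], lats[t + 1] = cand_lon[k], cand_lat[k]
        theta_prev = angles[k]

    # close the loop at the colony's launch point
    lons[-1], lats[-1] = lon0, lat0
    return TrueTrack(bird_id, colony.name, sex, times, lons, lats,
                     pd.Timestamp(start), pd.Timestamp(end))


def simulate_tracks(colonies, habitat: HabitatStack, movement_model: MovementModel,
                    n_birds: int, start_dates, end_dates, step_hours: int = 12,
                    seed: int = 0) -> list[TrueTrack]:
    """Simulate ``n_birds`` per colony between their start and end dates.

    ``start_dates``/``end_dates`` may be a single date-like or a mapping
    from colony name to date-like.  Bird sexes alternate M/F.  The top-level
    seed drives one independent stream per bird.
    """
    if n_birds < 0:
        raise ValueError("n_birds must be >= 0")
    colonies = list(colonies)
    tracks: list[TrueTrack] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(colonies) * max(n_birds, 1))
    k = 0
    for colony in colonies:
        start = start_dates[colony.name] if isinstance(start_dates, dict) else start_dates
        end = end_dates[colony.name] if isinstance(end_dates, dict) else end_dates
        for b in range(n_birds):
            rng = np.random.default_rng(children[k]); k += 1
            sex = "M" if b % 2 == 0 else "F"
            tracks.append(_simulate_one(f"{colony.name}_{b:03d}", colony, sex,
                                        habitat, movement_model, start, end,
                                        step_hours, rng))
    return tracks


@dataclass
class TwilightSeries:
    """Per-bird dawn/dusk event table.

    ``data`` columns: date (Timestamp, midnight UTC), event ('dawn'|'dusk'),
    hours (float, UTC hours since that date's midnight; may exceed 24),
    time (Timestamp), missing (bool, polar day/night), wet (bool, at sea).
    """

    bird_id: str
    data: pd.DataFrame
    twilight_elevation: float

    def events(self) -> pd.DataFrame:
        return self.data[~self.data["missing"]].reset_index(drop=True)


def simulate_twilights(track: TrueTrack, twilight_elevation=solar.DEFAULT_TWILIGHT_ELEVATION,
                       timing_noise_sd_minutes: float = 2.0, seed: int = 0) -> TwilightSeries:
    """Noisy dawn/dusk times along a track.

    For each calendar date the position nearest the event time provides the
    solar geometry; Gaussian timing noise (minutes) is added.  Dates with no
    twilight at the configured sun elevation (polar day/night) are emitted
    with ``missing=True``.
    """
    if not track.times.is_monotonic_increasing:
        raise ValueError("track must be time-ordered")
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(track.times.normalize().unique())
    rows = []
    tnum = np.asarray(track.times.view("int64"))
    for date in dates:
        doy = date.dayofyear
        # approximate event position: position nearest local noon of that date
        approx = date + pd.Timedelta(hours=12)
        i = int(np.argmin(np.abs(tnum - approx.value)))
        dawn_h, dusk_h = solar.twilight_hours_utc(doy, track.lons[i], track.lats[i],
                                                  twilight_elevation)
        for event, h in (("dawn", dawn_h), ("dusk", dusk_h)):
            missing = not np.isfinite(h)
            if not missing and timing_noise_sd_minutes > 0:
                h = h + rng.normal(0.0, timing_noise_sd_minutes / 60.0)
            rows.append({"date": date, "event": event,
                         "hours": np.nan if missing else float(h),
                         "time": pd.NaT if missing else date + pd.Timedelta(hours=float(h)),
                         "missing": missing, "wet": True})
    return TwilightSeries(track.bird_id, pd.DataFrame(rows), twilight_elevation)


def simulate_attendance(departure, return_date, span_start, span_end,
                        wet_at_sea: float = 0.95, wet_ashore: float = 0.04,
                        noise_sd: float = 0.03, seed: int = 0) -> pd.DataFrame:
    """Daily immersion (wet) fractions: dry ashore before departure and after
    return, wet at sea in between.  Columns: date, wet_fraction."""
    dates = pd.date_range(span_start, span_end, freq="D")
    departure = pd.Timestamp(departure)
    return_date = pd.Timestamp(return_date)
    rng = np.random.default_rng(seed)
    at_sea = (dates >= departure) & (dates < return_date)
    wf = np.where(at_sea, wet_at_sea, wet_ashore) + rng.normal(0, noise_sd, len(dates))
    return pd.DataFrame({"date": dates, "wet_fraction": np.clip(wf, 0.0, 1.0)})
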