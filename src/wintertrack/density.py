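"""Time-spent gridding and population density surfaces.

The time between two consecutive primary fixes is spread over 5000
possible intermediate locations sampled from speed-feasible paths between
the two posterior clouds (a Brownian-bridge-style interpolation whose
perpendicular spread is truncated to the reachability lens set by the
maximum plausible speed).  Intermediate weights sum exactly to the elapsed
time, so binning them on the 0.2 degree grid conserves total tracked time;
dividing by the grid total gives a proportion surface and multiplying by
the number of breeding birds (2 x pairs) gives bird density.  Gridding the
clouds directly provides the smoothing, so no kernel density estimation is
applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .environment import HabitatStack
from .geolocation import PosteriorTrack, PrimaryFix
from .grids import Grid, haversine_km
from .simulate import MovementModel

DEFAULT_N_INTERMEDIATE = 5000


class DensityError(RuntimeError):
    pass


@dataclass
class PointCloud:
    """Weighted intermediate-location set; weights are hours."""

    lons: np.ndarray
    lats: np.ndarray
    weights: np.ndarray

    @property
    def total_hours(self) -> float:
        return float(self.weights.sum())


@dataclass
class TimeSpentGrid:
    grid: Grid
    hours: np.ndarray           # (nlat, nlon)
    outside_hours: float
    n_birds: int

    @property
    def total_hours(self) -> float:
        return float(self.hours.sum()) + self.outside_hours


@dataclass
class DensitySurface:
    """Per-cell proportion of population time and bird density."""

    grid: Grid
    proportion: np.ndarray
    density: np.ndarray
    population_birds: int

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"proportion": (("lat", "lon"), self.proportion),
             "density": (("lat", "lon"), self.density,
                         {"units": "birds per cell"})},
            coords={"lon": self.grid.lon_centers, "lat": self.grid.lat_centers},
            attrs={"population_birds": self.population_birds,
                   **self.grid.to_dict()})

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "DensitySurface":
        ds = xr.open_dataset(path, engine="scipy").load()
        grid = Grid(float(ds.attrs["lon_min"]), float(ds.attrs["lat_min"]),
                    float(ds.attrs["resolution"]),
                    int(ds.attrs["nlon"]), int(ds.attrs["nlat"]))
        return cls(grid, ds["proportion"].values, ds["density"].values,
                   int(ds.attrs["population_birds"]))

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        m = ax.pcolormesh(self.grid.lon_edges, self.grid.lat_edges,
                          self.density, **kwargs)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        return m


def intermediate_cloud(fix_a: PrimaryFix, fix_b: PrimaryFix,
                       n_points: int = DEFAULT_N_INTERMEDIATE,
                       movement_model: MovementModel | None = None,
                       habitat: HabitatStack | None = None,
                       seed: int = 0, max_resample: int = 40) -> PointCloud:
    """Sample ``n_points`` intermediate locations between two fixes.

    Endpoints are drawn from the two posterior clouds; a point at path
    fraction u lies at the linear interpolate plus a perpendicular offset
    drawn from a zero-mean truncated normal bounded by the speed-feasibility
    lens (the ellipse with the endpoints as foci and string length
    max_speed * dt).  Each point carries weight dt / n_points hours.  Points
    on land/ice are resampled; endpoint pairs farther apart than the
    max-speed reach fall back to straight-line interpolation with a warning.
    """
    if fix_b.time <= fix_a.time:
        raise DensityError("fix_b must be later than fix_a")
    movement_model = movement_model or MovementModel()
    rng = np.random.default_rng(seed)
    dt = (fix_b.time - fix_a.time) / pd.Timedelta(hours=1)
    reach_km = movement_model.max_speed * dt
    month = fix_a.time.month

    def sample(k):
        ia = rng.choice(len(fix_a.lons), size=k, p=fix_a.weights)
        ib = rng.choice(len(fix_b.lons), size=k, p=fix_b.weights)
        a_lon, a_lat = fix_a.lons[ia], fix_a.lats[ia]
        b_lon, b_lat = fix_b.lons[ib], fix_b.lats[ib]
        d = haversine_km(a_lon, a_lat, b_lon, b_lat)
        too_far = d > reach_km
        if too_far.any():
            warnings.warn("endpoints beyond max-speed reach; "
                          "straight-line interpolation used for those draws")
        u = rng.uniform(0.0, 1.0, k)
        base_lon = a_lon + u * (b_lon - a_lon)
        base_lat = a_lat + u * (b_lat - a_lat)
        # feasibility lens half-width at fraction u (km)
        A = reach_km / 2.0
        c = d / 2.0
        with np.errstate(invalid="ignore"):
            B = np.sqrt(np.maximum(A ** 2 - c ** 2, 0.0))
            x = (u - 0.5) * d
            halfw = B * np.sqrt(np.maximum(1.0 - (x / np.maximum(A, 1e-9)) ** 2, 0.0))
        halfw = np.where(too_far, 0.0, halfw)
        off = rng.normal(0.0, 1.0, k) * (halfw / 2.0)
        off = np.clip(off, -halfw, halfw)
        # perpendicular unit vector in degree space (local km scaling)
        seg_lon_km = (b_lon - a_lon) * 111.32 * np.cos(np.radians(base_lat))
        seg_lat_km = (b_lat - a_lat) * 111.32
        norm = np.hypot(seg_lon_km, seg_lat_km)
        with np.errstate(invalid="ignore", divide="ignore"):
            perp_lon = np.where(norm > 0, -seg_lat_km / norm, 0.0)
            perp_lat = np.where(norm > 0, seg_lon_km / norm, 0.0)
        coslat = np.maximum(np.cos(np.radians(base_lat)), 1e-6)
        out_lon = base_lon + off * perp_lon / (111.32 * coslat)
        out_lat = base_lat + off * perp_lat / 111.32
        return out_lon, out_lat, base_lon, base_lat

    lons, lats, base_lon, base_lat = sample(n_points)
    if habitat is not None:
        for _ in range(max_resample):
            bad = habitat.is_blocked(lons, lats, month)
            if not bad.any():
                break
            nl, nt, bl, bt = sample(int(bad.sum()))
            lons[bad], lats[bad] = nl, nt
            base_lon[bad], base_lat[bad] = bl, bt
        bad = habitat.is_blocked(lons, lats, month)
        if bad.any():
            # fall back to the (unoffset) interpolates for stubborn points
            lons[bad], lats[bad] = base_lon[bad], base_lat[bad]
    weights = np.full(n_points, dt / n_points)
    return PointCloud(lons, lats, weights)


def track_clouds(track: PosteriorTrack, n_points: int = DEFAULT_N_INTERMEDIATE,
                 movement_model: MovementModel | None = None,
                 habitat: HabitatStack | None = None, seed: int = 0) -> list[PointCloud]:
    """Intermediate clouds for every consecutive fix pair of a track."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(max(len(track.fixes) - 1, 1))
    return [intermediate_cloud(a, b, n_points, movement_model, habitat,
                               seed=int(s) % (2 ** 31))
            for a, b, s in zip(track.fixes[:-1], track.fixes[1:], seeds)]


def accumulate_time(clouds, grid: Grid, n_birds: int | None = None) -> TimeSpentGrid:
    """Bin cloud weights (hours) into grid cells; half-open lower-left cells.

    Points outside the grid extent go to a reported outside bucket, never
    silently dropped.
    """
    clouds = list(clouds)
    if not clouds:
        raise DensityError("no clouds to accumulate")
    hours = np.zeros(grid.shape)
    outside = 0.0
    for cl in clouds:
        ilat, ilon, inside = grid.index(cl.lons, cl.lats)
        np.add.at(hours, (ilat[inside], ilon[inside]), cl.weights[inside])
        outside += float(cl.weights[~inside].sum())
    return TimeSpentGrid(grid, hours, outside, n_birds or len(clouds))


def to_density(tsg: TimeSpentGrid, population_birds: int) -> DensitySurface:
    """Proportion-of-time surface scaled to birds per cell."""
    if population_birds <= 0:
        raise DensityError("population_birds must be positive")
    total = float(tsg.hours.sum())
    if total <= 0:
        raise DensityError("time-spent grid has zero total time")
    proportion = tsg.hours / total
    return DensitySurface(tsg.grid, proportion, proportion * population_birds,
                          population_birds)
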