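"""Synthetic Southern Ocean habitat: gridded covariates, masks and water masses.

The analysis needs environmental rasters with the correlation structure a
habitat-selection model has to contend with: a dynamic-height field that is
nearly monotone with latitude (so water masses are zonal bands with frontal
wiggles), depth that shoals toward coasts, chlorophyll-a that is high over
northern shelf waters, a land mask, and monthly sea-ice masks (true where
ice cover exceeds 10%) that retreat as winter ends.  Fields are Gaussian
random fields (smoothed white noise, fixed correlation range) on top of
deterministic latitudinal trends, so everything is reproducible from one
seed.

Water-mass zones, from south to north:
``WS`` (Weddell Sea), ``SACCZ`` (Southern ACC Zone), ``PFZ`` (Polar Frontal
Zone), ``SAZ`` (Subantarctic Zone) and ``STZ`` (Subtropical Zone), obtained
by thresholding dynamic height at four monotone cut points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter

from .grids import Grid

#: zone labels ordered south -> north by increasing dynamic height
ZONES = ("WS", "SACCZ", "PFZ", "SAZ", "STZ")

#: months for which sea-ice masks are produced (April..August winter window)
ICE_MONTHS = (4, 5, 6, 7, 8)


@dataclass(frozen=True)
class ColonySpec:
    """A breeding colony: location and size in breeding pairs."""

    name: str
    lon: float
    lat: float
    pairs: int

    def __post_init__(self):
        if self.pairs <= 0:
            raise ValueError("pairs must be positive")

    @property
    def birds(self) -> int:
        """Breeding birds = 2 x pairs (the density surfaces scale by birds)."""
        return 2 * self.pairs


#: the three study colonies: macaroni penguins at Bird Island (South
#: Georgia) and southern rockhopper penguins at Steeple Jason and
#: Beauchene Islands (Falklands), with published breeding-pair counts.
DEFAULT_COLONIES = (
    ColonySpec("SMP", lon=-38.05, lat=-54.0167, pairs=408_000),
    ColonySpec("SRP", lon=-61.3833, lat=-51.0167, pairs=121_400),
    ColonySpec("BRP", lon=-59.21, lat=-52.92, pairs=105_800),
)

DEFAULT_ZONE_THRESHOLDS = (0.22, 0.42, 0.60, 0.78)


class HabitatStack:
    """Gridded habitat covariates + masks, backed by an xarray Dataset.

    Variables: ``depth`` (m, positive magnitude below sea level),
    ``dynamic_height`` (dimensionless), ``chla`` (mg m^-3), ``land_mask``
    (bool), ``ice_mask`` (bool, dim ``month``), ``water_mass`` (int codes
    into :data:`ZONES`).
    """

    def __init__(self, ds: xr.Dataset, grid: Grid):
        self.ds = ds
        self.grid = grid
        self._z_cache: dict[str, np.ndarray] = {}

    # -- convenience accessors -------------------------------------------
    @property
    def land(self) -> np.ndarray:
        return self.ds["land_mask"].values.astype(bool)

    @property
    def ocean(self) -> np.ndarray:
        return ~self.land

    def ice(self, month: int) -> np.ndarray:
        months = list(self.ds["month"].values)
        if month not in months:
            # outside the winter window: no ice constraint applied
            return np.zeros(self.grid.shape, dtype=bool)
        return self.ds["ice_mask"].values[months.index(month)].astype(bool)

    def layer(self, name: str) -> np.ndarray:
        return self.ds[name].values

    def zone_codes(self) -> np.ndarray:
        return self.ds["water_mass"].values

    def standardized(self, name: str) -> np.ndarray:
        """Layer z-scored over ocean cells (used for movement preference scores)."""
        if name not in self._z_cache:
            vals = self.ds[name].values
            oc = self.ocean
            z = (vals - vals[oc].mean()) / (vals[oc].std() + 1e-12)
            self._z_cache[name] = z
        return self._z_cache[name]

    def is_blocked(self, lons, lats, month: int) -> np.ndarray:
        """True where points fall outside the grid, on land, or on >10% ice."""
        ilat, ilon, inside = self.grid.index(lons, lats)
        blocked = ~inside
        ok = inside
        blk = self.land | self.ice(month)
        blocked = blocked | np.where(ok, blk[np.clip(ilat, 0, self.grid.nlat - 1),
                                         np.clip(ilon, 0, self.grid.nlon - 1)], False)
        return blocked

    def to_netcdf(self, path) -> None:
        self.ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "HabitatStack":
        ds = xr.open_dataset(path, engine="scipy").load()
        grid = Grid(float(ds.attrs["lon_min"]), float(ds.attrs["lat_min"]),
                    float(ds.attrs["resolution"]),
                    int(ds.attrs["nlon"]), int(ds.attrs["nlat"]))
        return cls(ds, grid)


def _grf(shape, range_cells, rng):
    """Unit-variance Gaussian random field via smoothed white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=range_cells, mode="nearest")
    return (f - f.mean()) / (f.std() + 1e-12)


def _default_land(grid: Grid, colonies) -> np.ndarray:
    """Synthetic coastline: a western continent, a southern ice-sheet coast,
    and one island cell per colony."""
    lon2d, lat2d = grid.center_mesh()
    land = np.zeros(grid.shape, dtype=bool)
    # South-America-like continent: western margin, widening northwards
    west_edge = -76.0 + 8.0 * (lat2d + 35.0) / -35.0  # -76 at -35S .. -68 at -70S? keep simple
    land |= (lon2d < np.minimum(-68.0, west_edge)) & (lat2d > -56.0)
    # Antarctic coast
    land |= lat2d < grid.lat_min + 2.0
    # colony islands
    for c in colonies:
        ilat, ilon, inside = grid.index(c.lon, c.lat)
        if inside:
            land[int(ilat), int(ilon)] = True
    return land


def make_environment(extent=(-85.0, 0.0, -70.0, -35.0), resolution=0.2,
                     zone_thresholds=DEFAULT_ZONE_THRESHOLDS, seed=0,
                     colonies=DEFAULT_COLONIES, range_cells=None) -> HabitatStack:
    """Generate a reproducible synthetic habitat stack.

    Parameters
    ----------
    extent : (lon_min, lon_max, lat_min, lat_max)
        Must cover the study region; the default spans 85W-0, 70S-35S.
    resolution : float
        Grid cell size in degrees; must divide the extent evenly.
    zone_thresholds : 4 ascending floats
        Dynamic-height cut points separating the five water masses.
    seed : int
        Single seed governing all random structure.
    range_cells : float, optional
        Correlation range of the random fields in cells; default scales
        with resolution so the physical range is resolution-independent.
    """
    thr = tuple(float(t) for t in zone_thresholds)
    if len(thr) != 4 or any(b <= a for a, b in zip(thr, thr[1:])):
        raise ValueError("zone_thresholds must be 4 strictly increasing values")
    grid = Grid.from_extent(*extent[:2], *extent[2:], resolution)
    rng = np.random.default_rng(seed)
    if range_cells is None:
        range_cells = max(2.0, 2.0 / resolution)  # ~2 degrees physical range

    lon2d, lat2d = grid.center_mesh()
    northness = (lat2d - grid.lat_min) / (grid.lat_max - grid.lat_min)

    land = _default_land(grid, colonies)

    # dynamic height: monotone with latitude + frontal perturbations
    dyn = northness + 0.06 * _grf(grid.shape, range_cells, rng)

    # depth: deep ocean shoaling toward land (shelf)
    from scipy.ndimage import distance_transform_edt
    dist_to_land = distance_transform_edt(~land)  # in cells
    shelf = np.exp(-dist_to_land / (6.0 / resolution * 0.2 + 3.0))
    depth = 4200.0 * (1.0 - 0.95 * shelf) + 500.0 * _grf(grid.shape, range_cells, rng)
    depth = np.clip(depth, 20.0, None)

    # chlorophyll-a: productive northern shelf, oligotrophic south, >= 0
    chla = np.exp(-1.0 + 1.6 * northness + 1.2 * shelf
                  + 0.5 * _grf(grid.shape, range_cells, rng))

    zones = np.digitize(dyn, thr)  # 0..4 -> WS..STZ

    # monthly ice edge retreating north through autumn/winter then held:
    # ice latitude threshold per month with ragged edge
    ice = np.zeros((len(ICE_MONTHS),) + grid.shape, dtype=bool)
    edge_by_month = {4: -66.0, 5: -64.5, 6: -63.0, 7: -61.5, 8: -60.0}
    ragged = 1.5 * _grf(grid.shape, range_cells, rng)
    for k, m in enumerate(ICE_MONTHS):
        ice[k] = lat2d < (edge_by_month[m] + ragged)

    ds = xr.Dataset(
        data_vars={
            "depth": (("lat", "lon"), depth,
                      {"units": "m", "positive": "down",
                       "long_name": "water depth magnitude"}),
            "dynamic_height": (("lat", "lon"), dyn,
                               {"long_name": "dynamic height index"}),
            "chla": (("lat", "lon"), chla,
                     {"units": "mg m-3", "long_name": "chlorophyll-a, pre-winter mean"}),
            "land_mask": (("lat", "lon"), land),
            "ice_mask": (("month", "lat", "lon"), ice,
                         {"long_name": "sea-ice cover > 10%"}),
            "water_mass": (("lat", "lon"), zones.astype(np.int8),
                           {"zones": " ".join(ZONES)}),
        },
        coords={"lon": grid.lon_centers, "lat": grid.lat_centers,
                "month": list(ICE_MONTHS)},
        attrs={"resolution": resolution, "lon_min": grid.lon_min,
               "lat_min": grid.lat_min, "nlon": grid.nlon, "nlat": grid.nlat,
               "zone_thresholds": list(thr), "seed": seed},
    )
    return HabitatStack(ds, grid)
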