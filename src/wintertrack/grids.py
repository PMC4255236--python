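"""Regular longitude/latitude grids and great-circle geometry.

All analysis surfaces (time-spent, density, habitat rasters) live on a
:class:`Grid`: a regular lon/lat lattice with half-open cells
``[lon, lon+res) x [lat, lat+res)`` anchored at the lower-left corner.
Arrays indexed on a grid are always ``(nlat, nlon)`` with row 0 at the
southern edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing (radians, clockwise from north)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def displace(lon, lat, bearing_rad, distance_km):
    """Move ``distance_km`` along ``bearing_rad`` from (lon, lat); returns (lon, lat).

    Uses the small-displacement local-tangent approximation, adequate for
    sub-daily movement steps (tens of km).
    """
    lat = np.asarray(lat, dtype=float)
    dlat = distance_km * np.cos(bearing_rad) / 111.32
    coslat = np.maximum(np.cos(np.radians(lat)), 1e-6)
    dlon = distance_km * np.sin(bearing_rad) / (111.32 * coslat)
    return np.asarray(lon, dtype=float) + dlon, lat + dlat


def wrap_lon(lon):
    """Wrap longitude to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat grid with half-open lower-left-anchored cells."""

    lon_min: float
    lat_min: float
    resolution: float
    nlon: int
    nlat: int

    @classmethod
    def from_extent(cls, lon_min: float, lon_max: float, lat_min: float,
                    lat_max: float, resolution: float) -> "Grid":
        """Build a grid covering the extent; the resolution must divide it evenly."""
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        nlon = (lon_max - lon_min) / resolution
        nlat = (lat_max - lat_min) / resolution
        if abs(nlon - round(nlon)) > 1e-8 or abs(nlat - round(nlat)) > 1e-8:
            raise ValueError(
                f"resolution {resolution} does not divide extent "
                f"({lon_min}..{lon_max}, {lat_min}..{lat_max}) evenly")
        return cls(lon_min, lat_min, resolution, int(round(nlon)), int(round(nlat)))

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.nlon * self.resolution

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nlat * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def n_cells(self) -> int:
        return self.nlat * self.nlon

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.resolution * np.arange(self.nlon + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.resolution * np.arange(self.nlat + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.nlon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.resolution * (np.arange(self.nlat) + 0.5)

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) cell-center meshes, shape (nlat, nlon)."""
        return np.meshgrid(self.lon_centers, self.lat_centers)

    def index(self, lons, lats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell indices (ilat, ilon) and an inside-mask for point arrays."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        ilon = np.floor((lons - self.lon_min) / self.resolution).astype(int)
        ilat = np.floor((lats - self.lat_min) / self.resolution).astype(int)
        inside = (ilon >= 0) & (ilon < self.nlon) & (ilat >= 0) & (ilat < self.nlat)
        return ilat, ilon, inside

    def cell_areas_km2(self) -> np.ndarray:
        """Approximate cell areas (km^2), shape (nlat, nlon); constant per row."""
        lat_c = np.radians(self.lat_centers)
        dlat_km = self.resolution * 111.32
        dlon_km = self.resolution * 111.32 * np.cos(lat_c)
        return np.repeat((dlat_km * dlon_km)[:, None], self.nlon, axis=1)

    def coarsen(self, factor: int) -> "Grid":
        if self.nlon % factor or self.nlat % factor:
            raise ValueError("factor must divide grid shape")
        return Grid(self.lon_min, self.lat_min, self.resolution * factor,
                    self.nlon // factor, self.nlat // factor)

    def to_dict(self) -> dict:
        return {"lon_min": self.lon_min, "lat_min": self.lat_min,
                "resolution": self.resolution, "nlon": self.nlon, "nlat": self.nlat}
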