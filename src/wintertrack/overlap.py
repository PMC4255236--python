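"""Isopleth ranges, interpopulation overlap indices and water-mass occupancy.

The 50% and 95% isopleths (core and peripheral range) are the smallest
sets of grid cells whose summed utilization mass reaches the level: cells
are ranked by density and accumulated until the level is enclosed, with
ties broken by cell index so the set is reproducible.  Two overlap indices
are computed on isopleth intersections:

* the percentage ``P_i`` of population i overlapping population j —
  by default the share of i's utilization mass (within its own isopleth)
  that falls inside the intersection, with a raw-area variant available;
* the encounter ratio ``R_ij`` — the ratio of the two populations' summed
  densities inside the intersection, an index of per-capita encounter
  rate (``R_ij = 1 / R_ji``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensitySurface
from .environment import HabitatStack, ZONES
from .grids import Grid


class OverlapError(RuntimeError):
    pass


@dataclass
class IsoplethSet:
    """Cells enclosing at least ``level`` percent of a population's mass."""

    population: str
    level: float
    cells: np.ndarray        # boolean (nlat, nlon)
    mass: float              # proportion actually enclosed

    def __contains__(self, other: "IsoplethSet") -> bool:  # pragma: no cover
        return bool((other.cells & ~self.cells).sum() == 0)

    def to_polygons(self):
        """Member cells dissolved into shapely polygons (WGS84 lon/lat)."""
        from shapely.geometry import box
        from shapely.ops import unary_union
        grid = self.cells  # local alias
        res = self._grid.resolution
        boxes = []
        ii, jj = np.nonzero(grid)
        lon_e = self._grid.lon_edges
        lat_e = self._grid.lat_edges
        for i, j in zip(ii, jj):
            boxes.append(box(lon_e[j], lat_e[i], lon_e[j + 1], lat_e[i + 1]))
        return unary_union(boxes) if boxes else None

    # grid is attached post-construction to keep the dataclass light
    _grid: Grid = None


def isopleth(surface: DensitySurface, level: float,
             population: str = "") -> IsoplethSet:
    """Minimal cell set enclosing ``level``% of the utilization mass.

    Cells are sorted by density descending (ties by flat cell index,
    ascending) and accumulated until the cumulative proportion reaches
    level/100.
    """
    if not 0.0 < level < 100.0:
        raise OverlapError("level must be in (0, 100)")
    prop = surface.proportion.ravel()
    total = prop.sum()
    if total <= 0:
        raise OverlapError("degenerate all-zero density surface")
    prop = prop / total
    order = np.lexsort((np.arange(prop.size), -prop))
    csum = np.cumsum(prop[order])
    k = int(np.searchsorted(csum, level / 100.0 - 1e-12)) + 1
    cells = np.zeros(prop.size, dtype=bool)
    cells[order[:k]] = True
    return IsoplethSet(population, level, cells.reshape(surface.grid.shape),
                       float(csum[k - 1]), _grid=surface.grid)


@dataclass
class OverlapResult:
    pop_i: str
    pop_j: str
    level: float
    intersection: np.ndarray
    p_i: float
    p_j: float
    r_ij: float   # NaN when intersection empty / denominator zero


def overlap_percentage(density_i: DensitySurface, iso_i: IsoplethSet,
                       iso_j: IsoplethSet, method: str = "mass") -> float:
    """Percentage of population i (within its isopleth) overlapping j.

    ``method='mass'`` (default): utilization-mass fraction
    100 * m_i(c_i n c_j) / m_i(c_i).  ``method='area'``: raw area fraction
    of the isopleth intersection, which the mass version reduces to for a
    uniform surface.
    """
    if iso_i.level != iso_j.level:
        raise OverlapError("isopleths must be at the same level")
    if not iso_i.cells.any():
        raise OverlapError("empty isopleth for population i")
    inter = iso_i.cells & iso_j.cells
    if method == "mass":
        denom = density_i.proportion[iso_i.cells].sum()
        if denom <= 0:
            raise OverlapError("population i has no mass inside its isopleth")
        return float(100.0 * density_i.proportion[inter].sum() / denom)
    elif method == "area":
        areas = density_i.grid.cell_areas_km2()
        return float(100.0 * areas[inter].sum() / areas[iso_i.cells].sum())
    raise OverlapError(f"unknown method {method!r}")


def encounter_ratio(density_i: DensitySurface, density_j: DensitySurface,
                    intersection: np.ndarray) -> float:
    """R_ij: ratio of summed bird densities of i and j inside the intersection."""
    if not intersection.any():
        raise OverlapError("intersection is empty; R undefined")
    num = float(density_i.density[intersection].sum())
    den = float(density_j.density[intersection].sum())
    if den <= 0:
        raise OverlapError("population j has zero density in the intersection")
    return num / den


def pairwise_overlap(surfaces: dict[str, DensitySurface],
                     levels=(50.0, 95.0), method: str = "mass") -> list[OverlapResult]:
    """All ordered-pair overlap results at each isopleth level."""
    results = []
    names = list(surfaces)
    isos = {(nm, lv): isopleth(surfaces[nm], lv, nm)
            for nm in names for lv in levels}
    for lv in levels:
        for i, ni in enumerate(names):
            for nj in names[i + 1:]:
                ii, jj = isos[(ni, lv)], isos[(nj, lv)]
                inter = ii.cells & jj.cells
                if inter.any():
                    p_i = overlap_percentage(surfaces[ni], ii, jj, method)
                    p_j = overlap_percentage(surfaces[nj], jj, ii, method)
                    r = encounter_ratio(surfaces[ni], surfaces[nj], inter)
                else:
                    p_i = p_j = 0.0
                    r = np.nan
                results.append(OverlapResult(ni, nj, lv, inter, p_i, p_j, r))
    return results


def water_mass_occupancy(surface: DensitySurface, habitat: HabitatStack) -> dict:
    """Percent of the population's mass in each water-mass zone.

    Ocean cells carry zone labels partitioning the domain; any mass on
    unlabelled (land) cells is reported under ``"unassigned"`` rather than
    dropped.  Percentages sum to 100.
    """
    zones = habitat.zone_codes()
    ocean = habitat.ocean
    total = surface.proportion.sum()
    if total <= 0:
        raise OverlapError("degenerate all-zero density surface")
    out = {}
    for code, name in enumerate(ZONES):
        sel = ocean & (zones == code)
        out[name] = float(100.0 * surface.proportion[sel].sum() / total)
    unassigned = float(100.0 * surface.proportion[~ocean].sum() / total)
    if unassigned > 0:
        out["unassigned"] = unassigned
    return out
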