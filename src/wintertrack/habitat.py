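"""Model-table construction: over-water distances and covariate extraction.

``cross_sea_distance`` computes, for every ocean cell, the shortest
over-water path length (km) from a colony, on the 8-neighbour cell graph
with great-circle step costs — cells behind land are reached around it,
and disconnected basins come back as infinite (flagged, never zero).

``build_model_table`` stacks one record per (ocean cell x population):
response ln(density + 1), habitat covariates, cross-sea distance, and the
competitor populations' densities with the self column aliased to exactly
zero (a population's density is never regressed on itself).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .density import DensitySurface
from .environment import ColonySpec, HabitatStack
from .grids import Grid, haversine_km


class HabitatError(RuntimeError):
    pass


def cross_sea_distance(grid: Grid, colony: ColonySpec,
                       land_mask: np.ndarray) -> np.ndarray:
    """Shortest over-water distance (km) from the colony to every ocean cell.

    Land cells get NaN; ocean cells unreachable from the colony get +inf.
    The source is the ocean cell nearest the colony (colonies sit on land).
    """
    ocean = ~np.asarray(land_mask, dtype=bool)
    if not ocean.any():
        raise HabitatError("no ocean cells")
    nlat, nlon = grid.shape
    idx2d = -np.ones(grid.shape, dtype=int)
    ii, jj = np.nonzero(ocean)
    idx2d[ii, jj] = np.arange(len(ii))
    lon_c = grid.lon_centers[jj]
    lat_c = grid.lat_centers[ii]

    rows, cols, costs = [], [], []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ni, nj = ii + di, jj + dj
            ok = (ni >= 0) & (ni < nlat) & (nj >= 0) & (nj < nlon)
            ok[ok] &= ocean[ni[ok], nj[ok]]
            a = idx2d[ii[ok], jj[ok]]
            b = idx2d[ni[ok], nj[ok]]
            w = haversine_km(lon_c[a], lat_c[a],
                             grid.lon_centers[nj[ok]], grid.lat_centers[ni[ok]])
            rows.append(a); cols.append(b); costs.append(w)
    g = coo_matrix((np.concatenate(costs),
                    (np.concatenate(rows), np.concatenate(cols))),
                   shape=(len(ii), len(ii))).tocsr()

    d_src = haversine_km(colony.lon, colony.lat, lon_c, lat_c)
    src = int(np.argmin(d_src))
    dist = dijkstra(g, directed=False, indices=src)
    out = np.full(grid.shape, np.nan)
    out[ii, jj] = dist
    return out


def build_model_table(surfaces: dict[str, DensitySurface], habitat: HabitatStack,
                      distances: dict[str, np.ndarray],
                      drop_unreachable: bool = True) -> pd.DataFrame:
    """One record per (ocean cell x population), ready for the GAM.

    Columns: population, lon, lat, cell, log_density (=ln(density+1)),
    depth, dynamic_height, chla, distance, and one competitor-density
    column per population (``dens_<name>``, ln(density+1) transformed, self
    aliased to zero).
    """
    grid = habitat.grid
    names = list(surfaces)
    for nm in names:
        if surfaces[nm].grid != grid or distances[nm].shape != grid.shape:
            raise HabitatError(f"grid mismatch for population {nm}")
    ocean = habitat.ocean
    ii, jj = np.nonzero(ocean)
    lon2d, lat2d = grid.center_mesh()
    base = {
        "cell": ii * grid.nlon + jj,
        "lon": lon2d[ii, jj], "lat": lat2d[ii, jj],
        "depth": habitat.layer("depth")[ii, jj],
        "dynamic_height": habitat.layer("dynamic_height")[ii, jj],
        "chla": habitat.layer("chla")[ii, jj],
    }
    logdens = {nm: np.log1p(surfaces[nm].density[ii, jj]) for nm in names}
    frames = []
    for nm in names:
        rec = dict(base)
        rec["population"] = nm
        rec["log_density"] = logdens[nm]
        rec["distance"] = distances[nm][ii, jj]
        for other in names:
            rec[f"dens_{other}"] = np.zeros(len(ii)) if other == nm else logdens[other]
        frames.append(pd.DataFrame(rec))
    out = pd.concat(frames, ignore_index=True)
    if drop_unreachable:
        n0 = len(out)
        out = out[np.isfinite(out["distance"])].reset_index(drop=True)
        out.attrs["dropped_unreachable"] = n0 - len(out)
    return out
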