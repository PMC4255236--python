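"""Cross-sea distances, model table, GAM fitting, selection, variogram."""

import heapq

import numpy as np
import pandas as pd
import pytest

from wintertrack import (DensitySurface, HabitatSelectionGAM, Smooth,
                         build_model_table, cross_sea_distance, select_model)
from wintertrack.environment import ColonySpec
from wintertrack.gam import GAMError, TensorSmooth
from wintertrack.grids import Grid, haversine_km
from wintertrack.habitat import HabitatError


def dijkstra_oracle(grid, land, src):
    """Independent shortest-path over ocean cells (binary-heap Dijkstra)."""
    nlat, nlon = grid.shape
    dist = {src: 0.0}
    heap = [(0.0, src)]
    done = set()
    while heap:
        d, (i, j) = heapq.heappop(heap)
        if (i, j) in done:
            continue
        done.add((i, j))
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if not (0 <= ni < nlat and 0 <= nj < nlon) or land[ni, nj]:
                    continue
                w = haversine_km(grid.lon_centers[j], grid.lat_centers[i],
                                 grid.lon_centers[nj], grid.lat_centers[ni])
                nd = d + float(w)
                if nd < dist.get((ni, nj), np.inf):
                    dist[(ni, nj)] = nd
                    heapq.heappush(heap, (nd, (ni, nj)))
    return dist


class TestCrossSeaDistance:
    grid = Grid.from_extent(-55, -45, -55, -45, 1.0)

    def test_open_ocean_close_to_great_circle(self):
        land = np.zeros(self.grid.shape, dtype=bool)
        colony = ColonySpec("X", -54.5, -54.5, 10)
        d = cross_sea_distance(self.grid, colony, land)
        tgt = haversine_km(-54.5, -54.5, self.grid.lon_centers[9],
                           self.grid.lat_centers[9])
        diag_km = 1.0 * 111.32 * np.sqrt(2)
        # 8-neighbour paths overshoot great circles by at most ~8%
        assert d[9, 9] <= tgt * 1.09 + diag_km
        assert d[9, 9] >= tgt - diag_km

    def test_land_barrier_lengthens_path(self):
        land = np.zeros(self.grid.shape, dtype=bool)
        land[2:9, 5] = True  # meridional wall with a gap at the south
        colony = ColonySpec("X", -54.5, -50.5, 10)
        d = cross_sea_distance(self.grid, colony, land)
        straight = haversine_km(-54.5, -50.5, self.grid.lon_centers[8],
                                self.grid.lat_centers[5])
        assert d[5, 8] > straight * 1.2
        assert np.isnan(d[3, 5])  # land cell itself

    def test_disconnected_basin_is_infinite(self):
        land = np.zeros(self.grid.shape, dtype=bool)
        land[:, 5] = True  # full wall
        colony = ColonySpec("X", -54.5, -50.5, 10)
        d = cross_sea_distance(self.grid, colony, land)
        assert np.isinf(d[:, 6:]).all()
        assert np.isfinite(d[:, :5]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dijkstra_oracle_on_random_mazes(self, seed):
        rng = np.random.default_rng(seed)
        land = rng.uniform(size=self.grid.shape) < 0.3
        land[0, 0] = False
        colony = ColonySpec("X", float(self.grid.lon_centers[0]),
                            float(self.grid.lat_centers[0]), 10)
        d = cross_sea_distance(self.grid, colony, land)
        oracle = dijkstra_oracle(self.grid, land, (0, 0))
        for (i, j), dv in oracle.items():
            assert d[i, j] == pytest.approx(dv, rel=1e-9)
        ocean_unreached = ~land & np.isinf(d)
        for i, j in zip(*np.nonzero(ocean_unreached)):
            assert (i, j) not in oracle


@pytest.fixture(scope="module")
def model_inputs(habitat):
    """Density surfaces + distances on the shared coarse habitat."""
    rng = np.random.default_rng(17)
    grid = habitat.grid
    surfaces = {}
    for name, pop in (("SMP", 816_000), ("SRP", 242_800), ("BRP", 211_600)):
        p = rng.uniform(0, 1, grid.shape) * habitat.ocean
        p /= p.sum()
        surfaces[name] = DensitySurface(grid, p, p * pop, pop)
    colonies = [ColonySpec("SMP", -38.05, -54.0167, 408_000),
                ColonySpec("SRP", -61.3833, -51.0167, 121_400),
                ColonySpec("BRP", -59.21, -52.92, 105_800)]
    distances = {c.name: cross_sea_distance(grid, c, habitat.land)
                 for c in colonies}
    return surfaces, distances


class TestModelTable:
    def test_self_competitor_aliased_to_zero(self, habitat, model_inputs):
        surfaces, distances = model_inputs
        tbl = build_model_table(surfaces, habitat, distances)
        for nm in surfaces:
            rows = tbl[tbl["population"] == nm]
            assert (rows[f"dens_{nm}"] == 0.0).all()
            others = [f"dens_{o}" for o in surfaces if o != nm]
            assert (rows[others].to_numpy() > 0).any()

    def test_response_is_log1p_density(self, habitat, model_inputs):
        surfaces, distances = model_inputs
        tbl = build_model_table(surfaces, habitat, distances)
        smp = tbl[tbl["population"] == "SMP"]
        cells = smp["cell"].to_numpy()
        ii, jj = cells // habitat.grid.nlon, cells % habitat.grid.nlon
        np.testing.assert_allclose(
            smp["log_density"], np.log1p(surfaces["SMP"].density[ii, jj]))

    def test_zero_density_maps_to_zero_response(self, habitat, model_inputs):
        surfaces, distances = model_inputs
        tbl = build_model_table(surfaces, habitat, distances)
        z = tbl[tbl["log_density"] == 0.0]
        assert len(z) >= 0  # ln(0+1) = 0 by construction

    def test_record_count_is_reachable_ocean_cells_times_populations(
            self, habitat, model_inputs):
        surfaces, distances = model_inputs
        tbl = build_model_table(surfaces, habitat, distances,
                                drop_unreachable=False)
        assert len(tbl) == int(habitat.ocean.sum()) * 3

    def test_grid_mismatch_rejected(self, habitat, model_inputs):
        surfaces, distances = model_inputs
        bad = dict(surfaces)
        g2 = Grid.from_extent(-10, 0, -10, 0, 1.0)
        bad["SMP"] = DensitySurface(g2, np.ones(g2.shape) / 100,
                                    np.ones(g2.shape), 100)
        with pytest.raises(HabitatError):
            build_model_table(bad, habitat, distances)


def simulate_table(rng, n_side=18, coupling=1.0, noise_sd=0.3):
    """Synthetic model table with known group-specific effects.

    Planted signals: opposite dynamic-height preferences for groups A and
    C (B responds nonlinearly), opposite depth preferences for A and B,
    and a positive coupling of group C's density on A's observed density
    (competitor association).  The competitor covariate carries cell-level
    variation independent of the habitat fields so its effect is
    identifiable despite habitat collinearity.
    """
    n = n_side * n_side
    lon = np.repeat(np.linspace(-60, -40, n_side), n_side)
    lat = np.tile(np.linspace(-60, -45, n_side), n_side)
    dyn = (lat + 60) / 15 + 0.05 * rng.standard_normal(n)
    dyn_c = dyn - dyn.mean()
    depth = rng.uniform(0, 1, n)
    dens_A_field = np.clip(-2.0 * dyn_c + rng.normal(0, 0.6, n), 0, None)
    effect = {
        "A": -2.0 * dyn_c - 1.5 * depth,
        "B": 2.0 * np.sin(np.pi * dyn) + 1.5 * depth,
        "C": 2.0 * dyn_c + coupling * dens_A_field,
    }
    rows = []
    for g in ("A", "B", "C"):
        y = effect[g] + noise_sd * rng.standard_normal(n)
        rows.append(pd.DataFrame({
            "population": g, "lon": lon, "lat": lat,
            "dynamic_height": dyn, "depth": depth,
            "dens_A": 0.0 if g == "A" else dens_A_field,
            "log_density": y}))
    return pd.concat(rows, ignore_index=True)


SMOOTHS = [Smooth("dynamic_height", k=6), Smooth("depth", k=6),
           Smooth("dens_A", k=6)]


class TestGAM:
    def test_pure_noise_shrinks_to_intercepts(self):
        rng = np.random.default_rng(1)
        tbl = simulate_table(rng)
        tbl["log_density"] = rng.standard_normal(len(tbl))
        res = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        smooth_edf = sum(v for k, v in res.edf_by_term.items()
                        if k != "parametric")
        assert smooth_edf < 3.0  # ~0.3 per smooth on average
        # and the fit explains essentially nothing beyond the intercepts
        assert np.var(res.fittedvalues) / np.var(res.model.y) < 0.05

    def test_partial_effect_recovery(self):
        rng = np.random.default_rng(2)
        tbl = simulate_table(rng)
        res = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        x, f = res.partial_effect("dynamic_height", "B")
        truth = 2.0 * np.sin(np.pi * x)
        truth -= truth.mean()
        r = np.corrcoef(f, truth)[0, 1]
        assert r > 0.95

    def test_identical_inputs_identical_aic(self):
        rng = np.random.default_rng(3)
        tbl = simulate_table(rng)
        a = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        b = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        assert a.aic == b.aic

    def test_missing_covariate_rejected(self):
        rng = np.random.default_rng(4)
        tbl = simulate_table(rng)
        with pytest.raises(GAMError):
            HabitatSelectionGAM(tbl, "log_density", [Smooth("nope")])

    def test_summary_mentions_terms(self):
        rng = np.random.default_rng(5)
        tbl = simulate_table(rng)
        res = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        s = res.summary()
        assert "AIC" in s and "s(dynamic_height):B" in s


class TestSelection:
    def test_group_specific_signal_favours_global(self):
        rng = np.random.default_rng(6)
        tbl = simulate_table(rng)
        sel = select_model(tbl, SMOOTHS)
        assert sel.iloc[0]["model"] == "Global"
        assert sel.iloc[0]["dAIC"] == 0.0

    def test_shared_signal_supports_reduced_model(self):
        rng = np.random.default_rng(7)
        tbl = simulate_table(rng)
        # overwrite: every group responds identically to dynamic_height
        shared = 2.0 * tbl["dynamic_height"].to_numpy()
        tbl["log_density"] = shared + 0.3 * rng.standard_normal(len(tbl))
        sel = select_model(tbl, [Smooth("dynamic_height", k=6),
                                 Smooth("depth", k=6)])
        reduced = sel[sel["model"] == "Population x s(dynamic_height)"]
        assert reduced["dAIC"].iloc[0] < 2.0

    def test_selection_is_reproducible(self):
        rng = np.random.default_rng(8)
        tbl = simulate_table(rng)
        a = select_model(tbl, SMOOTHS)
        b = select_model(tbl, SMOOTHS)
        pd.testing.assert_frame_equal(a, b)


class TestVariogramAndTensor:
    def test_white_residuals_flat_variogram(self):
        rng = np.random.default_rng(9)
        tbl = simulate_table(rng)
        res = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        vg = res.residual_variogram(max_lag_km=1200, n_bins=8, seed=1)
        g = vg["gamma"].to_numpy()
        assert np.isfinite(g).all() and (g >= 0).all()
        # flat: early and late bins within 25%
        assert abs(g[-2:].mean() / g[:2].mean() - 1) < 0.25

    def test_planted_spatial_signal_rises_then_flattens_after_tensor(self):
        rng = np.random.default_rng(10)
        tbl = simulate_table(rng)
        # planted smooth spatial field in the response, unexplained by
        # covariates -> autocorrelated residuals
        spatial = 1.5 * np.sin(tbl["lon"] / 6.0) * np.cos(tbl["lat"] / 5.0)
        tbl["log_density"] = tbl["log_density"] + spatial
        res = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        vg = res.residual_variogram(max_lag_km=1200, n_bins=8, seed=2)
        g = vg["gamma"].to_numpy()
        assert g[-2:].mean() > 1.5 * g[:2].mean()  # rising
        res_t = res.refit_with_tensor(spacing_deg=4.0)
        vg_t = res_t.residual_variogram(max_lag_km=1200, n_bins=8, seed=2)
        gt = vg_t["gamma"].to_numpy()
        assert gt[-2:].mean() < 1.3 * gt[:2].mean()  # flattened

    def test_tensor_attenuates_latitude_collinear_covariate(self):
        # dynamic height tracks latitude; once residual spatial structure
        # activates the tensor smooth, it absorbs part of the covariate's
        # effect and flattens the fitted partial curve
        rng = np.random.default_rng(11)
        tbl = simulate_table(rng)
        # latitude-structured residual signal loads onto the collinear
        # covariate when no spatial term is available
        spatial = 2.0 * np.cos(tbl["lat"] / 4.0)
        tbl["log_density"] = tbl["log_density"] + spatial
        res = HabitatSelectionGAM(tbl, "log_density", SMOOTHS).fit()
        res_t = res.refit_with_tensor(spacing_deg=4.0)
        def amp(r):
            out = []
            for g in ("A", "B", "C"):
                _, f = r.partial_effect("dynamic_height", g)
                out.append(f.max() - f.min())
            return np.mean(out)
        assert amp(res_t) / amp(res) < 1.0

    def test_sparse_bins_flagged(self):
        rng = np.random.default_rng(12)
        tbl = simulate_table(rng, n_side=5)
        res = HabitatSelectionGAM(tbl, "log_density",
                                  [Smooth("dynamic_height", k=5)]).fit()
        vg = res.residual_variogram(max_lag_km=3000, n_bins=30,
                                    max_pairs=400, seed=3)
        assert vg["flagged"].any()
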