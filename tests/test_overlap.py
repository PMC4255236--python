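"""Isopleths, overlap percentage P, encounter ratio R, water-mass occupancy."""

import numpy as np
import pytest

from wintertrack import (DensitySurface, encounter_ratio, isopleth,
                         overlap_percentage, pairwise_overlap,
                         water_mass_occupancy)
from wintertrack.grids import Grid
from wintertrack.overlap import OverlapError

GRID = Grid.from_extent(0, 10, 0, 10, 1.0)


def surface(prop, birds=1000):
    prop = np.asarray(prop, dtype=float)
    prop = prop / prop.sum()
    return DensitySurface(GRID, prop, prop * birds, birds)


def random_surface(rng, birds=1000, sparsity=0.3):
    p = rng.uniform(0, 1, GRID.shape)
    p[rng.uniform(size=GRID.shape) < sparsity] = 0.0
    if p.sum() == 0:
        p[0, 0] = 1.0
    return surface(p, birds)


def brute_force_isopleth(prop, level):
    """Independent oracle: k-largest-cells membership at minimal k."""
    flat = prop.ravel() / prop.sum()
    # stable sort descending with index tie-break
    order = sorted(range(flat.size), key=lambda i: (-flat[i], i))
    total, members = 0.0, set()
    for i in order:
        members.add(i)
        total += flat[i]
        if total >= level / 100.0 - 1e-12:
            break
    mask = np.zeros(flat.size, dtype=bool)
    mask[list(members)] = True
    return mask.reshape(prop.shape)


class TestIsopleth:
    def test_single_occupied_cell(self):
        p = np.zeros(GRID.shape)
        p[3, 4] = 1.0
        s = surface(p)
        for lv in (50, 95):
            iso = isopleth(s, lv)
            assert iso.cells.sum() == 1 and iso.cells[3, 4]

    def test_uniform_surface_half_cells(self):
        s = surface(np.ones(GRID.shape))
        iso = isopleth(s, 50)
        assert iso.cells.sum() == 50

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("level", [50, 95])
    def test_matches_brute_force_oracle(self, seed, level):
        rng = np.random.default_rng(seed)
        s = random_surface(rng)
        iso = isopleth(s, level)
        np.testing.assert_array_equal(
            iso.cells, brute_force_isopleth(s.proportion, level))

    @pytest.mark.parametrize("seed", range(10))
    def test_nesting_and_minimality(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_surface(rng)
        core = isopleth(s, 50)
        periph = isopleth(s, 95)
        assert not (core.cells & ~periph.cells).any()  # 50% within 95%
        for iso, lv in ((core, 50), (periph, 95)):
            members = s.proportion[iso.cells]
            assert members.sum() / s.proportion.sum() >= lv / 100 - 1e-12
            # dropping the least-dense member breaks the level
            assert ((members.sum() - members.min()) / s.proportion.sum()
                    < lv / 100)

    def test_all_zero_surface_fails(self):
        s = DensitySurface(GRID, np.zeros(GRID.shape), np.zeros(GRID.shape), 10)
        with pytest.raises(OverlapError):
            isopleth(s, 50)


class TestOverlapPercentage:
    def test_contained_isopleth_is_100(self):
        p = np.zeros(GRID.shape)
        p[2:4, 2:4] = 1.0
        s_i = surface(p)
        q = np.zeros(GRID.shape)
        q[1:6, 1:6] = 1.0
        s_j = surface(q)
        iso_i, iso_j = isopleth(s_i, 95), isopleth(s_j, 95)
        assert overlap_percentage(s_i, iso_i, iso_j) == pytest.approx(100.0)

    def test_disjoint_is_zero(self):
        p = np.zeros(GRID.shape); p[0:2, 0:2] = 1.0
        q = np.zeros(GRID.shape); q[8:10, 8:10] = 1.0
        s_i, s_j = surface(p), surface(q)
        assert overlap_percentage(s_i, isopleth(s_i, 95),
                                  isopleth(s_j, 95)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(200 + seed)
        s_i, s_j = random_surface(rng), random_surface(rng)
        iso_i, iso_j = isopleth(s_i, 50), isopleth(s_j, 50)
        got = overlap_percentage(s_i, iso_i, iso_j)
        num = den = 0.0
        for a in range(10):
            for b in range(10):
                if iso_i.cells[a, b]:
                    den += s_i.proportion[a, b]
                    if iso_j.cells[a, b]:
                        num += s_i.proportion[a, b]
        assert got == pytest.approx(100.0 * num / den if den else 0.0)

    def test_enlarging_other_isopleth_never_decreases_p(self):
        rng = np.random.default_rng(42)
        s_i, s_j = random_surface(rng), random_surface(rng)
        import dataclasses
        iso_i = isopleth(s_i, 50)
        iso_j = isopleth(s_j, 50)
        # enlarge c_j (its 95% set relabelled) and require P_i not to drop
        iso_j_big = dataclasses.replace(isopleth(s_j, 95), level=50)
        p_small = overlap_percentage(s_i, iso_i, iso_j)
        p_big = overlap_percentage(s_i, iso_i, iso_j_big)
        assert p_big >= p_small - 1e-12

    def test_area_variant_reduces_to_area_fraction(self):
        p = np.ones(GRID.shape)
        s_i = surface(p)
        q = np.zeros(GRID.shape); q[0:5, :] = 1.0
        s_j = surface(q)
        iso_i = isopleth(s_i, 95)   # 95 cells of uniform i
        iso_j = isopleth(s_j, 95)   # within the southern half
        mass = overlap_percentage(s_i, iso_i, iso_j, method="mass")
        area = overlap_percentage(s_i, iso_i, iso_j, method="area")
        assert mass == pytest.approx(area, rel=0.02)


class TestEncounterRatio:
    def test_identical_surfaces_unit_ratio(self):
        rng = np.random.default_rng(1)
        s = random_surface(rng)
        inter = isopleth(s, 95).cells
        assert encounter_ratio(s, s, inter) == pytest.approx(1.0)

    def test_linear_scaling(self):
        rng = np.random.default_rng(2)
        s_i, s_j = random_surface(rng), random_surface(rng)
        inter = isopleth(s_i, 95).cells & isopleth(s_j, 95).cells
        r = encounter_ratio(s_i, s_j, inter)
        s_i3 = DensitySurface(GRID, s_i.proportion, 3 * s_i.density,
                              3 * s_i.population_birds)
        assert encounter_ratio(s_i3, s_j, inter) == pytest.approx(3 * r)

    @pytest.mark.parametrize("seed", range(10))
    def test_antisymmetry_and_brute_force(self, seed):
        rng = np.random.default_rng(300 + seed)
        s_i, s_j = random_surface(rng, 1000), random_surface(rng, 3000)
        inter = isopleth(s_i, 95).cells & isopleth(s_j, 95).cells
        if not inter.any():
            pytest.skip("disjoint draw")
        r_ij = encounter_ratio(s_i, s_j, inter)
        r_ji = encounter_ratio(s_j, s_i, inter)
        assert r_ij * r_ji == pytest.approx(1.0)
        num = sum(s_i.density[a, b] for a in range(10) for b in range(10)
                  if inter[a, b])
        den = sum(s_j.density[a, b] for a in range(10) for b in range(10)
                  if inter[a, b])
        assert r_ij == pytest.approx(num / den)

    def test_empty_intersection_flagged(self):
        rng = np.random.default_rng(3)
        s = random_surface(rng)
        with pytest.raises(OverlapError):
            encounter_ratio(s, s, np.zeros(GRID.shape, dtype=bool))


class TestPairwise:
    def test_result_invariants(self):
        rng = np.random.default_rng(5)
        surfaces = {"A": random_surface(rng), "B": random_surface(rng)}
        for r in pairwise_overlap(surfaces):
            assert 0 <= r.p_i <= 100 and 0 <= r.p_j <= 100
            if not r.intersection.any():
                assert r.p_i == r.p_j == 0 and np.isnan(r.r_ij)


class TestOccupancy:
    def test_all_mass_in_one_zone(self, habitat):
        z = habitat.zone_codes()
        oc = habitat.ocean
        prop = np.zeros(habitat.grid.shape)
        prop[oc & (z == 4)] = 1.0  # STZ only
        s = DensitySurface(habitat.grid, prop / prop.sum(),
                           prop / prop.sum() * 100, 100)
        occ = water_mass_occupancy(s, habitat)
        assert occ["STZ"] == pytest.approx(100.0)
        assert all(occ[k] == 0 for k in ("WS", "SACCZ", "PFZ", "SAZ"))

    def test_percentages_sum_to_100(self, habitat):
        rng = np.random.default_rng(6)
        prop = rng.uniform(0, 1, habitat.grid.shape) * habitat.ocean
        s = DensitySurface(habitat.grid, prop / prop.sum(),
                           prop / prop.sum() * 500, 500)
        occ = water_mass_occupancy(s, habitat)
        assert sum(occ.values()) == pytest.approx(100.0, abs=1e-6)
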