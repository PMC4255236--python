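# wintertrack

Winter-distribution analysis for crested penguins tracked with light-level
geolocators (GLS).  The package is aimed at movement ecologists who want a
tested, scriptable version of the classic GLS winter-range workflow:
light-based positioning, Bayesian track smoothing under a speed prior,
time-spent density surfaces, isopleth range overlap between populations,
and habitat-selection modelling with competitor-density covariates.
Because real tag archives are rarely redistributable, a first-class
synthetic-data module simulates colonies, habitat rasters, dispersive
migration and the resulting tag observables, so the whole pipeline can be
exercised — and its statistical behaviour verified — offline.

## The analysis

**Geolocation.** A GLS tag records light and immersion.  Longitude comes
from local apparent noon: the dawn/dusk midpoint, corrected by the
equation of time, offset from 12:00 UTC at 15°/h.  Latitude comes from day
length via the sunrise hour-angle equation

  cos H = (sin h₀ − sin φ sin δ) / (cos φ cos δ),

with δ the solar declination and h₀ the twilight sun-elevation threshold
(default −3.44°).  Near the equinoxes day length is ~12 h at every
latitude, so latitude is unidentifiable; fixes outside the 24 April –
20 August window are discarded.  Raw twice-daily estimates are then
smoothed by Metropolis-within-Gibbs MCMC (five chains of 1000 iterations
after a 500-iteration burn-in) whose posterior combines Gaussian error on
twilight times, a zero-truncated normal prior on travel speed (mean
3 km h⁻¹, SD 1.8 — the winter swimming speed of southern rockhopper
penguins), and zero mass on land or on the month-matched >10% sea-ice
mask.

**Density.** The time between consecutive fixes is spread over 5000
speed-feasible intermediate locations per fix pair, binned on a 0.2° grid.
The binned hours divided by the grid total give a proportion surface;
multiplied by the number of breeding birds (2 × pairs) they give bird
density.  Gridding the clouds themselves provides the smoothing — no
kernel density estimation is applied.

**Overlap.** The 50% and 95% isopleths (core and peripheral range) are the
minimal cell sets enclosing that share of a population's utilization mass.
For populations *i, j* with isopleths c_i, c_j:

  P_i = 100 · m_i(c_i ∩ c_j) / m_i(c_i)   (percent of *i* overlapping *j*)
  R_ij = Σ_{c_i ∩ c_j} D_i / Σ_{c_i ∩ c_j} D_j  (per-capita encounter ratio)

where m_i is utilization mass and D the bird-density surface.

**Habitat selection.** Cell-level log(density + 1) is modelled by a
Gaussian additive model: population factor intercepts plus, for each
covariate (cross-sea distance from the colony, depth, dynamic height,
chlorophyll-a, and each competitor population's density, self-aliased to
zero), a population-specific cubic shrinkage smooth.  Backward AIC
selection removes population × smooth interactions one at a time, and a
4° × 4° latitude–longitude tensor smooth can be added to absorb residual
spatial autocorrelation (diagnosed with an empirical semivariogram).

## Worked example

```python
import numpy as np
import wintertrack as wt
from wintertrack.environment import DEFAULT_COLONIES
from wintertrack.geolocation import PosteriorTrack, PrimaryFix

# winter phenology from colony departure/return dates
print("SRP male winter:", wt.winter_duration("2011-04-17", "2011-10-16"), "days")

# simulate a small tracking season and build density surfaces
habitat = wt.make_environment(resolution=1.0, seed=0)
prefs = {"SMP": {"dynamic_height": -5.0, "depth": 3.0},
         "SRP": {"dynamic_height": 18.0, "depth": -4.0, "chla": 3.0},
         "BRP": {"dynamic_height": 5.0}}
surfaces = {}
for colony in DEFAULT_COLONIES:
    mm = wt.MovementModel(habitat_preference=prefs[colony.name])
    tracks = wt.simulate_tracks([colony], habitat, mm, n_birds=4,
                                start_dates="2011-04-24",
                                end_dates="2011-08-20", seed=0)
    clouds = []
    for tr in tracks:
        fixes = [PrimaryFix(t, "dawn", np.array([lo]), np.array([la]),
                            np.array([1.0]))
                 for t, lo, la in zip(tr.times, tr.lons, tr.lats)]
        clouds += wt.track_clouds(PosteriorTrack(tr.bird_id, fixes),
                                  n_points=500, movement_model=mm,
                                  habitat=habitat, seed=1)
    tsg = wt.accumulate_time(clouds, habitat.grid)
    surfaces[colony.name] = wt.to_density(tsg, colony.birds)

for r in wt.pairwise_overlap(surfaces, levels=(95.0,)):
    print(f"{r.pop_i} vs {r.pop_j}: P_{r.pop_i}={r.p_i:.1f}% "
          f"P_{r.pop_j}={r.p_j:.1f}% R={r.r_ij:.2f}")
occ = wt.water_mass_occupancy(surfaces["SRP"], habitat)
print("SRP occupancy (%):", {k: round(v, 1) for k, v in occ.items()})
```

Output:

```
SRP male winter: 182 days
SMP vs SRP: P_SMP=0.0% P_SRP=0.0% R=nan
SMP vs BRP: P_SMP=0.0% P_BRP=0.0% R=nan
SRP vs BRP: P_SRP=30.7% P_BRP=1.4% R=26.05
SRP occupancy (%): {'WS': 0.0, 'SACCZ': 0.0, 'PFZ': 31.4, 'SAZ': 54.4, 'STZ': 14.1}
```

Reading this: the Steeple Jason rockhopper winter (17 April → 16 October)
lasts 182 days.  At this small simulation scale the macaroni population
(SMP) is spatially disjoint from both Falklands populations (P = 0, R
undefined), while the two rockhopper populations' peripheral ranges
intersect: 30.7% of SRP's utilization mass lies in the shared area versus
1.4% of BRP's, and within that area SRP outnumber BRP 26:1 per cell.  The
occupancy row shows SRP mass concentrated in subantarctic and frontal-zone
waters.  Density totals always equal the population sizes (e.g. BRP:
2 × 105,800 pairs = 211,600 birds) because the proportion surface sums to
one by construction.

The same pipeline is scriptable end to end:

```sh
wintertrack run-all --config config.yaml --seed 1 --outdir out/
```

which writes tracks, twilights, smoothed fixes, density rasters (NetCDF),
isopleth polygons (GeoJSON), overlap/occupancy tables, the model-selection
ladder and phenology windows (CSV), each stamped with the config hash.

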