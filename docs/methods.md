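# Methods

This note documents the models, numerical choices and limitations behind
`wintertrack`, in the order the pipeline runs them.

## Synthetic study conditions

The simulator reproduces the statistical structure the analysis must cope
with, not real geography.  Its defaults are the study conditions used
throughout the tests:

* **Colonies.** Three colonies with the published coordinates and sizes:
  SMP (macaroni penguins, Bird Island, 54.017° S 38.05° W, 408,000 pairs),
  SRP (southern rockhoppers, Steeple Jason, 51.017° S 61.383° W, 121,400
  pairs) and BRP (southern rockhoppers, Beauchêne, 52.92° S 59.21° W,
  105,800 pairs).  Beauchêne's source coordinate is printed as
  "52°92′ S", which is not a valid arcminute value; we read it as decimal
  degrees.  Population scaling uses birds = 2 × pairs; only ratios matter
  downstream and the factor is recorded on the surface object.
* **Environment.** Fields on a configurable grid (default 0.2°, 85° W–0°,
  70–35° S): dynamic height = a northward linear trend plus a Gaussian
  random field (smoothed white noise, ~2° correlation range); water-mass
  zones (WS, SACCZ, PFZ, SAZ, STZ) by thresholding dynamic height at four
  monotone cuts, so zones are zonal bands with frontal wiggles and dynamic
  height is strongly collinear with latitude — deliberately, because that
  collinearity is the main modelling nuisance the tensor-smooth machinery
  exists for.  Depth shoals exponentially toward coasts; chlorophyll-a is
  log-normal, elevated over northern shelf water, and represents the
  pre-winter (January–mid-April) productivity field.  Land is a stylized
  western continent, a southern ice-sheet coast and one island cell per
  colony.  Monthly ice masks (>10% cover) advance northward April→August
  with a ragged edge.
* **Movement.** Steps every 12 h (matching twice-daily fixes).  Speeds are
  drawn from a zero-truncated normal whose *post-truncation* mean and SD
  equal 3 and 1.8 km h⁻¹; the underlying location/scale are solved
  numerically, since truncating N(3, 1.8²) at zero would inflate the mean
  to ≈3.19.  (When sd ≥ 0.75 × mean that moment system has no solution —
  the zero-truncated family cannot reach such coefficients of variation —
  and the code falls back to truncating N(mean, sd) directly, which is
  also the correct diffuse-prior limit.)  Headings are chosen by softmax
  over 24 candidate bearings scored by persistence (von-Mises-like
  concentration term), a linear habitat-preference score on z-scored
  covariate layers, and a homing term that ramps up when the remaining
  time approaches the time needed to swim home, so tracks start and end
  at the colony's launch point (the nearest ocean cell center — colonies
  themselves sit on land).  Candidates on land/ice are excluded; if all
  are blocked the step is retried at half and quarter distance, and a bird
  whose cell is engulfed by the advancing monthly ice mask jumps toward
  the nearest open cell.  The per-colony preference weights default to
  values that reproduce the qualitative zonal segregation of the three
  real populations (SMP south of the Polar Front, SRP in
  subtropical/subantarctic shelf water, BRP intermediate); they were
  chosen once, by inspection of simulated occupancy tables, and are
  configuration, not fitted quantities.
* **Observables.** For each track date, dawn and dusk times from solar
  geometry (Spencer's declination and equation-of-time expansions,
  accurate to ~0.1°/~0.6 min) at the position nearest local noon, plus
  Gaussian timing noise (default SD 2 min); polar day/night dates are
  flagged missing.  Daily wet/dry immersion fractions are ~0.95 at sea
  and ~0.04 ashore with Gaussian jitter.

What the simulator does **not** emulate: real bathymetry or altimetry,
light-curve shape and shading (twilight errors are i.i.d. Gaussian in
time, real ones are skewed and weather-correlated), sub-daily immersion
microstructure, tag failure, and sex differences in movement.  Passing
tests therefore demonstrate the pipeline's internal correctness and its
statistical behaviour under a known truth — not field accuracy on real
tags.

## Geolocation

Longitude: dawn/dusk midpoint = local apparent noon; lon = 15 · (12 −
EoT/60 − noon_UTC), wrapped to [−180, 180).  Latitude: the sunrise
hour-angle equation is solved in closed form as A sin φ + B cos φ = C;
the hemisphere argument selects the branch.  Days with |δ| < 6° are
flagged unidentifiable — the date-window analogue is discarding data
outside 24 April – 20 August (a 119-day window), which the pipeline also
applies.  Day lengths implying |cos H| > 1 are flagged beyond the twilight
limit.  The twilight sun-elevation threshold (default −3.44°) and the
observation-error SD are configuration, not constants.

The smoother samples per-fix positions by Metropolis-within-Gibbs:
Gaussian random-walk proposals (0.35° SD), log-posterior = Gaussian
twilight-time likelihood + truncated-normal speed penalty between
adjacent fixes + hard land/ice masks (month-matched: a fix uses the ice
mask of its calendar month).  Because the speed penalty couples only
adjacent fixes, odd- and even-indexed fixes are conditionally independent
blocks; the sampler updates them in alternating "red-black" sweeps so the
whole track vectorizes, leaving the stationary distribution unchanged.
Defaults are five chains of 1000 post-burn-in iterations (500 burn-in,
thinned by 2); convergence is summarized by a split-chain variance ratio
per fix/coordinate with threshold 1.1, and failure raises a warning and a
`converged=False` flag, never a silent pass.  Credible-region coverage is
assessed empirically: a point is inside the level-q region of a cloud if
its Mahalanobis distance from the cloud mean is below the cloud's own
q-quantile of distances.

## Density surfaces

Intermediate locations between fixes a and b follow a Brownian-bridge-like
law: endpoint draws from the two clouds, a uniform path fraction u, and a
perpendicular offset drawn from a truncated normal whose bound is the
half-width of the speed-feasibility lens — the ellipse with foci a, b and
string length v_max·Δt, v_max = mean + 4 SD = 10.2 km h⁻¹ (the offset SD is
half the local bound).  The 5000 points per pair are equally weighted at
Δt/5000 hours each, so the cloud's mass is exactly the elapsed time;
endpoint pairs beyond the reach fall back to straight-line interpolation
with a warning.  Masked points are resampled (up to 40 rounds, then placed
on the unoffset interpolate).  Binning uses half-open lower-left-anchored
cells, which makes 2×2 aggregation of a half-resolution grid reproduce the
coarse binning bit-for-bit; points outside the grid go to a reported
"outside" bucket.  Proportion = hours / in-grid total; density =
proportion × birds.  No kernel smoothing anywhere: the posterior clouds
are the smoothing.

## Overlap statistics

Isopleths are computed by sorting cells by density (ties broken by flat
cell index, so the set is reproducible) and accumulating until the level
is enclosed; this greedy set is provably minimal for mass accumulation and
is cross-checked against an independent k-largest-cells oracle in the
tests.  P is implemented as the mass fraction of population i inside
c_i ∩ c_j normalized by its mass inside c_i, which reduces to the area
fraction for uniform surfaces; an area-based variant is available via
`method="area"` because the source presentation of the formula is
ambiguous between the two.  R is the ratio of summed densities over the
intersection — the reading under which R is not simply determined by the
P values and population sizes.  Statistics are computed on cell sets;
polygons are derived afterwards only for GeoJSON export, avoiding
polygon-precision artefacts.

## Habitat-selection model

One record per (ocean cell × population): response ln(density + 1),
covariates depth, dynamic height, chl-a, shortest over-water distance from
the colony (Dijkstra on the 8-neighbour ocean-cell graph with great-circle
edge costs; unreachable cells are +inf and dropped with a count, never
zeroed), and each population's ln(density + 1) as competitor covariates
with the self column aliased to exactly zero.  SST is not a covariate (it
is collinear with dynamic height and not produced by the simulator).

Smooths are cubic P-splines (default 10 basis functions, equally spaced
knots, second-difference penalty) with a small identity component added to
the penalty so λ → ∞ shrinks a term — including its linear part — to zero:
shrinkage smooths that can select themselves out.  Group-specific smooths
are the basis columns masked and centered within each population.  Each
block has its own smoothing parameter, selected by coordinate descent on a
log-spaced grid (10⁻³…10⁶, two sweeps) minimizing GCV with an
effective-d.f. inflation factor γ = 1.4, the standard remedy for GCV
undersmoothing; the procedure is deterministic for given data, so
identical tables give identical AICs.  AIC uses the Gaussian log-likelihood
with total effective degrees of freedom (trace of the coefficient-space
influence matrix) plus one for the residual variance — hence fractional
model d.f.  Basis objects are shared across the model variants of one
selection run so their AICs are comparable.

Selection fits the global model (every covariate × population), then each
single-interaction removal (shared smooth replaces the three
population-specific ones), then — for removals that beat the global model
on AIC — full-variable drops.  Both ladders, without and with the spatial
tensor smooth, are emitted.  The tensor is a P-spline tensor product on
longitude and latitude with 4° knot spacing and a Kronecker-sum penalty.
The residual semivariogram γ(h) = ½·mean[(r_a − r_b)²] is estimated on
subsampled point pairs (default 2·10⁵) in great-circle lag bins; bins with
fewer than 30 pairs are flagged.  With latitude-structured residual signal
the variogram rises with lag and the tensor refit flattens it — and, when
a covariate is collinear with latitude, the tensor visibly attenuates that
covariate's partial-effect amplitude, which is why partial effects should
be interpreted from the tensor-free fit.

## Phenology

Sub-daily immersion is aggregated to a daily wet fraction; a day is ashore
when that fraction is below 0.5.  The winter window requires an initial
ashore (moult) run and a terminal ashore run of at least 5 days each,
separated by a sustained wet run: departure is the first day of that wet
run, return the first day of the terminal dry run, and duration is the
exact calendar-day difference.  The run-length rule is our choice — the
demarcation is described only as "clear" in the source literature — and on
clean series it is insensitive to ±0.1 threshold changes, which the tests
assert.

## Pipeline

Stages (environment → simulate → geolocate → grid → overlap → model →
phenology) each write their artefacts plus a manifest entry keyed by the
SHA-256 hash of the canonical config JSON; re-running a stage whose
outputs exist under the same hash is a no-op, giving cheap resumability.
Smoothed fix clouds are persisted as a 100-sample-per-fix CSV subsample —
full clouds (thousands of draws per fix) stay in memory within a run.

## Problem sizes used in the checks

The test suite and the acceptance script run the pipeline at reduced but
statistically meaningful sizes, chosen so every property is exercised at
honest power: 1° grids, 12-bird conservation runs, 100 randomized 10×10
toy grids for the brute-force oracle comparisons, 20-seed coverage studies
of the smoother (10-day stationary tracks, full five-chain sampler), and
20 replicates of the planted-preference model-recovery study on 18×18
cell tables.  The conservation identities (time, population mass,
occupancy percentages) are scale-free and hold to rounding error at any
size.

## Known limitations

* Longitude and latitude are estimated from a day's twilight pair as if
  the bird were stationary within the day; for a moving bird this smears
  the raw estimate by up to a few tens of km, which the smoother's speed
  prior is designed to absorb.
* The GCV coordinate descent finds a good, not provably global, λ
  configuration; AIC comparisons between near-tied models (ΔAIC ≲ 2)
  should not be over-read.
* Great-circle geometry uses a spherical Earth (haversine) and local
  planar displacement for sub-daily steps; errors are ≲0.2% at the scales
  involved.
* The empirical Mahalanobis credible-region rule assumes roughly convex
  unimodal clouds; for strongly curved posteriors (e.g. along ice edges)
  coverage can dip a few percent below nominal.
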