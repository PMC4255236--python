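"""Light-level geolocation: threshold estimates, MCMC smoothing, equinox windows.

The raw estimators invert the solar geometry in :mod:`wintertrack.solar`:
longitude from the offset of local apparent noon (dawn/dusk midpoint,
corrected by the equation of time) against UTC noon, latitude from day
length via the sunrise hour-angle equation.  Near the equinoxes day length
is ~12 h at every latitude, so latitude is unidentifiable; days whose
solar declination magnitude is below a threshold are flagged and the
analysis discards everything outside the 24 April - 20 August window.

Raw twice-daily estimates are then smoothed by a Bayesian model whose
posterior combines (a) Gaussian error on the observed twilight *times*,
(b) a zero-truncated-normal prior on travel speed between consecutive
fixes (mean 3, SD 1.8 km/h), and (c) zero mass on land and on the
month-matched >10% sea-ice mask.  Sampling is Metropolis-within-Gibbs over
per-fix positions, run as five chains of 1000 iterations after a 500
iteration burn-in; odd/even fixes are updated in alternating blocks (the
speed prior couples only adjacent fixes, so the blocks are conditionally
independent and can be vectorized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .environment import HabitatStack
from .grids import haversine_km, wrap_lon
from .simulate import MovementModel, TwilightSeries


class GeolocationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# raw threshold estimators

def longitude_from_noon(dawn_time, dusk_time, date=None) -> float:
    """Longitude (degrees E, wrapped to [-180, 180)) from a dawn/dusk pair.

    The twilight midpoint is local apparent noon; its offset from 12:00 UTC,
    corrected by the equation of time, maps to longitude at 15 deg/hour.
    """
    dawn_time = pd.Timestamp(dawn_time)
    dusk_time = pd.Timestamp(dusk_time)
    if dusk_time <= dawn_time:
        raise GeolocationError("dusk must follow dawn within one solar day")
    if date is None:
        date = dawn_time.normalize()
    midpoint = dawn_time + (dusk_time - dawn_time) / 2
    mid_hours = (midpoint - pd.Timestamp(date).normalize()) / pd.Timedelta(hours=1)
    eot = float(solar.equation_of_time_minutes(pd.Timestamp(date).dayofyear))
    return float(wrap_lon(15.0 * (12.0 - eot / 60.0 - mid_hours)))


@dataclass(frozen=True)
class LatitudeEstimate:
    value: float  # degrees N; NaN unless status == "ok"
    status: str   # "ok" | "unidentifiable" | "beyond_limit"


def latitude_from_daylength(day_length_hours: float, date,
                            twilight_elevation=solar.DEFAULT_TWILIGHT_ELEVATION,
                            hemisphere: str = "south",
                            declination_threshold_deg: float = 6.0) -> LatitudeEstimate:
    """Latitude from day length on a given date.

    Solves  sin(h0) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(H)
    for phi, with H the half-day-length hour angle.  The two algebraic
    branches are disambiguated by the requested hemisphere.  When
    ``|delta|`` is below ``declination_threshold_deg`` the equation is too
    flat in phi (the equinox problem) and the estimate is flagged
    unidentifiable; a day length implying ``|cos H| > 1`` is beyond the
    twilight limit (polar day/night boundary) and flagged.
    """
    if not 0.0 < day_length_hours < 24.0:
        raise GeolocationError("day_length must be in (0, 24) hours")
    doy = pd.Timestamp(date).dayofyear
    decl = float(solar.solar_declination_deg(doy))
    if abs(decl) < declination_threshold_deg:
        return LatitudeEstimate(np.nan, "unidentifiable")
    h0 = np.radians(twilight_elevation)
    H = np.radians(day_length_hours / 2.0 * 15.0)
    d = np.radians(decl)
    # A sin(phi) + B cos(phi) = C
    A, B, C = np.sin(d), np.cos(d) * np.cos(H), np.sin(h0)
    R = np.hypot(A, B)
    if abs(C) > R:
        return LatitudeEstimate(np.nan, "beyond_limit")
    psi = np.arctan2(B, A)
    base = np.arcsin(C / R)
    candidates = [np.degrees(base - psi) if abs(base - psi) <= np.pi / 2 else np.nan,
                  np.degrees(np.pi - base - psi)
                  if abs(np.pi - base - psi) <= np.pi / 2 else np.nan]
    candidates = [c for c in candidates if np.isfinite(c) and abs(c) <= 90.0]
    if not candidates:
        return LatitudeEstimate(np.nan, "beyond_limit")
    want_south = hemisphere.lower().startswith("s")
    sel = [c for c in candidates if (c <= 0) == want_south] or candidates
    # prefer the branch matching the hemisphere; among several take extreme
    return LatitudeEstimate(float(min(sel) if want_south else max(sel)), "ok")


def raw_positions(twilights: TwilightSeries, hemisphere: str = "south",
                  declination_threshold_deg: float = 6.0) -> pd.DataFrame:
    """Twice-daily raw fixes from a twilight series.

    Each day's dawn/dusk pair yields one (lon, lat) estimate; it is
    attached to both of that day's twilight events (the primary-fix
    instants).  Columns: time, event, date, lon, lat, lat_status.
    """
    ev = twilights.data
    rows = []
    for date, grp in ev.groupby("date"):
        dawn = grp[(grp["event"] == "dawn") & ~grp["missing"]]
        dusk = grp[(grp["event"] == "dusk") & ~grp["missing"]]
        if len(dawn) == 0 or len(dusk) == 0:
            continue
        dawn_h = float(dawn["hours"].iloc[0])
        dusk_h = float(dusk["hours"].iloc[0])
        if dusk_h <= dawn_h:
            continue
        mid = (dawn_h + dusk_h) / 2.0
        eot = float(solar.equation_of_time_minutes(pd.Timestamp(date).dayofyear))
        lon = float(wrap_lon(15.0 * (12.0 - eot / 60.0 - mid)))
        lat_est = latitude_from_daylength(
            dusk_h - dawn_h, date, twilights.twilight_elevation,
            hemisphere, declination_threshold_deg)
        for _, r in grp[~grp["missing"]].iterrows():
            rows.append({"time": r["time"], "event": r["event"], "date": date,
                         "obs_dawn_hours": dawn_h, "obs_dusk_hours": dusk_h,
                         "lon": lon, "lat": lat_est.value,
                         "lat_status": lat_est.status})
    if not rows:
        raise GeolocationError("no usable twilight pairs")
    return pd.DataFrame(rows).sort_values("time").reset_index(drop=True)


# ---------------------------------------------------------------------------
# posterior track containers

@dataclass
class PrimaryFix:
    """Position posterior at one twilight instant."""

    time: pd.Timestamp
    event: str
    lons: np.ndarray
    lats: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if len(self.lons) < 1:
            raise ValueError("fix needs at least one sample")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        self.weights = w / w.sum()

    @property
    def lon(self) -> float:
        return float(np.sum(self.weights * self.lons))

    @property
    def lat(self) -> float:
        return float(np.sum(self.weights * self.lats))

    def covers(self, lon: float, lat: float, level: float = 0.9) -> bool:
        """Is (lon, lat) inside the empirical ``level`` credible region?

        Uses the Mahalanobis-depth rule: the point is covered if its
        Mahalanobis distance from the cloud is below the cloud's own
        ``level`` quantile of distances.
        """
        pts = np.column_stack([self.lons, self.lats])
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T) + 1e-12 * np.eye(2)
        icov = np.linalg.inv(cov)
        d = np.einsum("ij,jk,ik->i", pts - mu, icov, pts - mu)
        d0 = float((np.array([lon, lat]) - mu) @ icov @ (np.array([lon, lat]) - mu))
        return d0 <= np.quantile(d, level)


@dataclass
class PosteriorTrack:
    bird_id: str
    fixes: list[PrimaryFix]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [f.time for f in self.fixes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("fixes must be strictly time-ordered")

    def __len__(self):
        return len(self.fixes)

    def point_estimates(self) -> pd.DataFrame:
        return pd.DataFrame({"time": [f.time for f in self.fixes],
                             "event": [f.event for f in self.fixes],
                             "lon": [f.lon for f in self.fixes],
                             "lat": [f.lat for f in self.fixes]})


@dataclass(frozen=True)
class EquinoxWindows:
    """Calendar window unaffected by the equinox problem (month, day)."""

    spring_cutoff: tuple[int, int] = (4, 24)   # 24 April
    autumn_cutoff: tuple[int, int] = (8, 20)   # 20 August

    def __post_init__(self):
        if self.spring_cutoff >= self.autumn_cutoff:
            raise ValueError("spring cutoff must precede autumn cutoff")

    def contains(self, ts: pd.Timestamp) -> bool:
        md = (ts.month, ts.day)
        return self.spring_cutoff <= md <= self.autumn_cutoff


def apply_equinox_windows(track: PosteriorTrack,
                          windows: EquinoxWindows = EquinoxWindows()):
    """Drop fixes outside the reliable window; returns (track, n_removed)."""
    kept = [f for f in track.fixes if windows.contains(f.time)]
    removed = len(track.fixes) - len(kept)
    if not kept:
        warnings.warn(f"{track.bird_id}: no fixes remain inside the equinox window")
    diag = dict(track.diagnostics, equinox_removed=removed)
    return PosteriorTrack(track.bird_id, kept, diag), removed


# ---------------------------------------------------------------------------
# MCMC smoother

def _speed_logpdf_factory(model: MovementModel):
    dist = model.speed_dist
    def logpdf(speed):
        with np.errstate(divide="ignore"):
            return dist.logpdf(np.maximum(speed, 0.0))
    return logpdf


def _obs_loglik(lon, lat, doy, obs_dawn, obs_dusk, sd_hours, elevation):
    """Twilight-time observation log-likelihood (unnormalized), vectorized."""
    dawn, dusk = solar.twilight_hours_utc(doy, lon, lat, elevation)
    ll = np.zeros(np.shape(lon), dtype=float)
    bad = ~np.isfinite(dawn)  # polar day/night at the proposed latitude
    for pred, obs in ((dawn, obs_dawn), (dusk, obs_dusk)):
        have = np.isfinite(obs)
        ll = ll - np.where(have & ~bad, 0.5 * ((pred - obs) / sd_hours) ** 2, 0.0)
    return np.where(bad, -1e12, ll)


def _split_rhat(samples: np.ndarray) -> float:
    """Split-chain variance-ratio convergence indicator for (chains, draws)."""
    c, n = samples.shape
    half = n // 2
    if half < 2:
        return np.inf
    segs = samples[:, :half], samples[:, half:2 * half]
    means = np.concatenate([s.mean(axis=1) for s in segs])
    vars_ = np.concatenate([s.var(axis=1, ddof=1) for s in segs])
    W = vars_.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((half - 1) / half + B / (W * half)))


def smooth_positions(raw: pd.DataFrame, movement_model: MovementModel,
                     habitat: HabitatStack, obs_sd_minutes: float = 4.0,
                     twilight_elevation=solar.DEFAULT_TWILIGHT_ELEVATION,
                     chains: int = 5, iterations: int = 1000, burnin: int = 500,
                     proposal_sd_deg: float = 0.35, seed: int = 0,
                     bird_id: str = "bird", rhat_threshold: float = 1.1,
                     thin: int = 2) -> PosteriorTrack:
    """Smooth raw twice-daily estimates into per-fix posterior clouds.

    ``raw`` is the output of :func:`raw_positions` (needs columns time,
    event, date, obs_dawn_hours, obs_dusk_hours, lon, lat, lat_status).
    Returns a :class:`PosteriorTrack` whose clouds pool the post-burn-in
    draws of all chains; ``diagnostics['converged']`` reports the
    split-chain variance-ratio check (threshold ``rhat_threshold``) and a
    warning is emitted — never silence — if it fails.
    """
    raw = raw.sort_values("time").reset_index(drop=True)
    n = len(raw)
    if n < 2:
        raise GeolocationError("need at least two raw estimates to smooth")

    times = pd.DatetimeIndex(raw["time"])
    doy = solar.day_of_year(times.values).astype(float)
    months = times.month.to_numpy()
    obs_dawn = raw["obs_dawn_hours"].to_numpy(dtype=float)
    obs_dusk = raw["obs_dusk_hours"].to_numpy(dtype=float)
    dt_hours = np.diff(times.view("int64")) / 3.6e12
    if (dt_hours <= 0).any():
        raise GeolocationError("raw estimates must be strictly time-ordered")
    sd_hours = obs_sd_minutes / 60.0
    speed_logpdf = _speed_logpdf_factory(movement_model)

    # initial state: raw estimates, latitude gaps interpolated
    lon0 = raw["lon"].to_numpy(dtype=float)
    lat0 = pd.Series(raw["lat"].to_numpy(dtype=float)).interpolate(
        limit_direction="both").fillna(habitat.grid.lat_centers.mean()).to_numpy()
    # nudge starting points off masked cells
    blocked0 = habitat.is_blocked(lon0, lat0, int(months[0]))
    if blocked0.any():
        ok = ~blocked0
        if not ok.any():
            raise GeolocationError("no unmasked starting position available")
        idx_ok = np.flatnonzero(ok)
        for i in np.flatnonzero(blocked0):
            j = idx_ok[np.argmin(np.abs(idx_ok - i))]
            lon0[i], lat0[i] = lon0[j], lat0[j]

    rng = np.random.default_rng(seed)
    pos = np.empty((chains, n, 2))
    pos[:, :, 0] = lon0 + rng.normal(0, 0.2, (chains, n))
    pos[:, :, 1] = lat0 + rng.normal(0, 0.2, (chains, n))
    for c in range(chains):  # ensure valid start cells per chain
        for i in range(n):
            if habitat.is_blocked(pos[c, i, 0], pos[c, i, 1], int(months[i])):
                pos[c, i] = (lon0[i], lat0[i])

    def local_logpost(lon, lat, idx, cur_pos):
        """Posterior terms touching fixes ``idx`` (per chain, vectorized)."""
        ll = _obs_loglik(lon, lat, doy[idx], obs_dawn[idx], obs_dusk[idx],
                         sd_hours, twilight_elevation)
        has_left = idx - 1 >= 0
        if has_left.any():
            li = idx[has_left]
            d = haversine_km(cur_pos[:, li - 1, 0], cur_pos[:, li - 1, 1],
                             lon[:, has_left], lat[:, has_left])
            ll[:, has_left] += speed_logpdf(d / dt_hours[li - 1])
        has_right = idx + 1 < n
        if has_right.any():
            ri = idx[has_right]
            d = haversine_km(lon[:, has_right], lat[:, has_right],
                             cur_pos[:, ri + 1, 0], cur_pos[:, ri + 1, 1])
            ll[:, has_right] += speed_logpdf(d / dt_hours[ri])
        # masks: -inf on land / monthly ice
        flat_lon = lon.ravel()
        flat_lat = lat.ravel()
        blocked = np.zeros(flat_lon.shape, dtype=bool)
        mlist = months[idx]
        for m in np.unique(mlist):
            sel = np.tile(mlist == m, lon.shape[0])
            blocked[sel] = habitat.is_blocked(flat_lon[sel], flat_lat[sel], int(m))
        ll = ll + np.where(blocked.reshape(lon.shape), -np.inf, 0.0)
        return ll

    n_keep = (iterations - 1) // thin + 1
    kept = np.empty((chains, n_keep, n, 2), dtype=np.float32)
    colors = [np.arange(0, n, 2), np.arange(1, n, 2)]
    total_iters = burnin + iterations
    k_out = 0
    for it in range(total_iters):
        for idx in colors:
            cur_lon = pos[:, idx, 0]
            cur_lat = pos[:, idx, 1]
            prop_lon = cur_lon + rng.normal(0, proposal_sd_deg, cur_lon.shape)
            prop_lat = cur_lat + rng.normal(0, proposal_sd_deg, cur_lat.shape)
            ll_cur = local_logpost(cur_lon, cur_lat, idx, pos)
            ll_prop = local_logpost(prop_lon, prop_lat, idx, pos)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.uniform(size=cur_lon.shape)) < (ll_prop - ll_cur)
            pos[:, idx, 0] = np.where(accept, prop_lon, cur_lon)
            pos[:, idx, 1] = np.where(accept, prop_lat, cur_lat)
        if it >= burnin and (it - burnin) % thin == 0:
            kept[:, k_out] = pos
            k_out += 1
    kept = kept[:, :k_out]

    rhats = []
    for i in range(n):
        for d in range(2):
            rhats.append(_split_rhat(kept[:, :, i, d].astype(float)))
    max_rhat = float(np.nanmax(rhats))
    converged = max_rhat < rhat_threshold
    if not converged:
        warnings.warn(f"{bird_id}: chains may not have converged "
                      f"(max split-Rhat {max_rhat:.3f} >= {rhat_threshold})")

    fixes = []
    for i in range(n):
        cloud = kept[:, :, i, :].reshape(-1, 2).astype(float)
        w = np.full(len(cloud), 1.0 / len(cloud))
        fixes.append(PrimaryFix(times[i], raw["event"].iloc[i],
                                cloud[:, 0], cloud[:, 1], w))
    diags = {"chains": chains, "iterations": iterations, "burnin": burnin,
             "thin": thin, "max_rhat": max_rhat, "converged": converged}
    return PosteriorTrack(bird_id, fixes, diags)
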