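"""End-to-end pipeline: simulate -> geolocate -> grid -> overlap -> model.

Each stage writes its artefacts into the configured output directory and
records itself in ``manifest.json`` together with the config hash; a stage
whose outputs already exist under the same config hash is skipped, which
makes runs resumable stage by stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .config import PipelineConfig
from .density import accumulate_time, to_density, track_clouds, DensitySurface
from .environment import make_environment, HabitatStack
from .gam import Smooth, selection_tables, select_model, HabitatSelectionGAM
from .geolocation import (EquinoxWindows, apply_equinox_windows, raw_positions,
                          smooth_positions)
from .habitat import build_model_table, cross_sea_distance
from .overlap import isopleth, pairwise_overlap, water_mass_occupancy
from .phenology import detect_winter_window
from .simulate import (MovementModel, simulate_attendance, simulate_tracks,
                       simulate_twilights)

log = logging.getLogger("wintertrack")

STAGES = ("environment", "simulate", "geolocate", "grid", "overlap",
          "model", "phenology")


class PipelineError(RuntimeError):
    pass


class _Manifest:
    def __init__(self, outdir: Path, cfg_hash: str):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_hash") != cfg_hash:
                self.data = {"config_hash": cfg_hash, "stages": {}}
        else:
            self.data = {"config_hash": cfg_hash, "stages": {}}

    def done(self, stage: str, outputs: list[str]) -> None:
        self.data["stages"][stage] = {"outputs": outputs,
                                      "finished": time.strftime("%Y-%m-%dT%H:%M:%S")}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))

    def is_done(self, stage: str, outdir: Path) -> bool:
        rec = self.data["stages"].get(stage)
        return bool(rec) and all((outdir / f).exists() for f in rec["outputs"])


def run_pipeline(config: PipelineConfig, resume: bool = True,
                 stages=STAGES) -> dict:
    """Run the configured stages; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(outdir, config.hash())
    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str))

    state: dict = {}
    for stage in stages:
        if resume and man.is_done(stage, outdir):
            log.info("stage %s: up to date, skipping", stage)
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FNS[stage](config, outdir, state)
        except Exception as e:
            raise PipelineError(f"stage {stage!r} failed "
                                f"(config {config.hash()}): {e}") from e
        man.done(stage, outputs)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return man.data


# --- stages ----------------------------------------------------------------

def _get_habitat(config, outdir, state) -> HabitatStack:
    if "habitat" not in state:
        path = outdir / "environment.nc"
        if path.exists():
            state["habitat"] = HabitatStack.from_netcdf(path)
        else:
            state["habitat"] = make_environment(
                config.extent, config.resolution, seed=config.seed,
                colonies=config.colony_specs())
    return state["habitat"]


def _stage_environment(config, outdir, state):
    hab = make_environment(config.extent, config.resolution, seed=config.seed,
                           colonies=config.colony_specs())
    hab.to_netcdf(outdir / "environment.nc")
    state["habitat"] = hab
    return ["environment.nc"]


def _movement_for(config, colony_name) -> MovementModel:
    pref = config.preferences.get(colony_name, {})
    return MovementModel(config.mean_speed, config.speed_sd, dict(pref),
                         config.turning_concentration)


def _stage_simulate(config, outdir, state):
    hab = _get_habitat(config, outdir, state)
    tracks = []
    for i, colony in enumerate(config.colony_specs()):
        tracks += simulate_tracks(
            [colony], hab, _movement_for(config, colony.name), config.n_birds,
            config.start_date, config.end_date, seed=config.seed + 1000 + i)
    twilights = [simulate_twilights(t, config.twilight_elevation,
                                    config.twilight_noise_sd_minutes,
                                    seed=config.seed + 2000 + k)
                 for k, t in enumerate(tracks)]
    wio.write_tracks_csv(tracks, outdir / "tracks.csv")
    wio.write_twilights_csv(twilights, outdir / "twilights.csv")
    state["tracks"], state["twilights"] = tracks, twilights
    return ["tracks.csv", "twilights.csv"]


def _stage_geolocate(config, outdir, state):
    hab = _get_habitat(config, outdir, state)
    if "twilights" not in state:
        state["twilights"] = wio.read_twilights_csv(outdir / "twilights.csv")
    windows = EquinoxWindows(tuple(config.equinox_spring),
                             tuple(config.equinox_autumn))
    model = MovementModel(config.mean_speed, config.speed_sd)
    posts = []
    for k, tw in enumerate(state["twilights"]):
        raw = raw_positions(tw)
        post = smooth_positions(
            raw, model, hab, obs_sd_minutes=config.obs_sd_minutes,
            twilight_elevation=config.twilight_elevation, chains=config.chains,
            iterations=config.iterations, burnin=config.burnin,
            seed=config.seed + 3000 + k, bird_id=tw.bird_id)
        post, _ = apply_equinox_windows(post, windows)
        posts.append(post)
    pd.concat([p.point_estimates().assign(bird_id=p.bird_id) for p in posts],
              ignore_index=True).to_csv(outdir / "fixes_smoothed.csv", index=False)
    wio.write_fix_clouds_csv(posts, outdir / "fix_clouds.csv",
                             seed=config.seed + 3500)
    state["posterior_tracks"] = posts
    return ["fixes_smoothed.csv", "fix_clouds.csv"]


def _stage_grid(config, outdir, state):
    hab = _get_habitat(config, outdir, state)
    if "posterior_tracks" not in state:
        state["posterior_tracks"] = wio.read_fix_clouds_csv(outdir / "fix_clouds.csv")
    model = MovementModel(config.mean_speed, config.speed_sd)
    surfaces = {}
    outputs = []
    for colony in config.colony_specs():
        birds = [p for p in state["posterior_tracks"]
                 if p.bird_id.startswith(colony.name)]
        clouds = []
        for k, p in enumerate(birds):
            clouds += track_clouds(p, config.n_intermediate, model, hab,
                                   seed=config.seed + 4000 + k)
        tsg = accumulate_time(clouds, hab.grid, n_birds=len(birds))
        surf = to_density(tsg, colony.birds)
        surf.to_netcdf(outdir / f"density_{colony.name}.nc")
        outputs.append(f"density_{colony.name}.nc")
        surfaces[colony.name] = surf
    state["surfaces"] = surfaces
    return outputs


def _get_surfaces(config, outdir, state):
    if "surfaces" not in state:
        state["surfaces"] = {
            c.name: DensitySurface.from_netcdf(outdir / f"density_{c.name}.nc")
            for c in config.colony_specs()}
    return state["surfaces"]


def _stage_overlap(config, outdir, state):
    hab = _get_habitat(config, outdir, state)
    surfaces = _get_surfaces(config, outdir, state)
    isos = [isopleth(s, lv, nm) for nm, s in surfaces.items()
            for lv in config.isopleth_levels]
    wio.isopleths_to_geojson(isos, outdir / "isopleths.geojson")
    res = pairwise_overlap(surfaces, config.isopleth_levels)
    pd.DataFrame([{"pop_i": r.pop_i, "pop_j": r.pop_j, "level": r.level,
                   "P_i": r.p_i, "P_j": r.p_j, "R_ij": r.r_ij}
                  for r in res]).to_csv(outdir / "overlap.csv", index=False)
    occ = {nm: water_mass_occupancy(s, hab) for nm, s in surfaces.items()}
    pd.DataFrame(occ).to_csv(outdir / "occupancy.csv")
    return ["isopleths.geojson", "overlap.csv", "occupancy.csv"]


def _stage_model(config, outdir, state):
    hab = _get_habitat(config, outdir, state)
    surfaces = _get_surfaces(config, outdir, state)
    distances = {c.name: cross_sea_distance(hab.grid, c, hab.land)
                 for c in config.colony_specs()}
    table = build_model_table(surfaces, hab, distances)
    table.to_csv(outdir / "model_table.csv", index=False)
    smooths = [Smooth(v, k=config.basis_dim) for v in
               ["distance", "depth", "dynamic_height", "chla"]
               + [f"dens_{c.name}" for c in config.colony_specs()]]
    if config.fit_tensor_ladder:
        sel = selection_tables(table, smooths,
                               tensor_spacing_deg=config.tensor_spacing_deg)
    else:
        sel = select_model(table, smooths)
        sel.insert(0, "tensor", False)
    sel.to_csv(outdir / "selection.csv", index=False)
    res = HabitatSelectionGAM(table, "log_density", smooths).fit()
    rows = []
    for sm in smooths:
        for g in sorted(table["population"].unique()):
            x, f = res.partial_effect(sm.var, g)
            rows.append(pd.DataFrame({"term": sm.var, "population": g,
                                      "x": x, "effect": f}))
    pd.concat(rows, ignore_index=True).to_csv(outdir / "partials.csv", index=False)
    res.residual_variogram().to_csv(outdir / "variogram.csv", index=False)
    return ["model_table.csv", "selection.csv", "partials.csv", "variogram.csv"]


def _stage_phenology(config, outdir, state):
    rows = []
    for i, colony in enumerate(config.colony_specs()):
        ph = config.phenology.get(colony.name)
        if ph is None:
            continue
        dep, ret = pd.Timestamp(ph["departure"]), pd.Timestamp(ph["return"])
        att = simulate_attendance(dep, ret, dep - pd.Timedelta(days=30),
                                  ret + pd.Timedelta(days=30),
                                  seed=config.seed + 5000 + i)
        win = detect_winter_window(att)
        rows.append({"colony": colony.name, "departure": win.departure.date(),
                     "return": win.return_date.date(),
                     "duration_days": win.duration_days})
    pd.DataFrame(rows).to_csv(outdir / "phenology.csv", index=False)
    return ["phenology.csv"]


_STAGE_FNS = {"environment": _stage_environment, "simulate": _stage_simulate,
              "geolocate": _stage_geolocate, "grid": _stage_grid,
              "overlap": _stage_overlap, "model": _stage_model,
              "phenology": _stage_phenology}
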