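"""CSV / NetCDF / GeoJSON plumbing for pipeline artefacts."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .geolocation import PosteriorTrack, PrimaryFix


def write_tracks_csv(tracks, path) -> None:
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(path, index=False)


def write_twilights_csv(series_list, path) -> None:
    frames = []
    for tw in series_list:
        df = tw.data.copy()
        df.insert(0, "bird_id", tw.bird_id)
        df["twilight_elevation"] = tw.twilight_elevation
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_twilights_csv(path):
    from .simulate import TwilightSeries
    df = pd.read_csv(path, parse_dates=["date", "time"])
    out = []
    for bird_id, grp in df.groupby("bird_id", sort=False):
        elev = float(grp["twilight_elevation"].iloc[0])
        out.append(TwilightSeries(
            str(bird_id),
            grp.drop(columns=["bird_id", "twilight_elevation"])
               .reset_index(drop=True), elev))
    return out


def write_fix_clouds_csv(tracks: list[PosteriorTrack], path,
                         samples_per_fix: int = 100, seed: int = 0) -> None:
    """Smoothed fixes with a per-fix subsample of the posterior cloud."""
    rng = np.random.default_rng(seed)
    rows = []
    for tr in tracks:
        for k, f in enumerate(tr.fixes):
            m = min(samples_per_fix, len(f.lons))
            sel = rng.choice(len(f.lons), size=m, replace=False, p=None)
            for s in sel:
                rows.append((tr.bird_id, k, f.time, f.event,
                             f.lons[s], f.lats[s], 1.0 / m))
    pd.DataFrame(rows, columns=["bird_id", "fix", "time", "event",
                                "lon", "lat", "weight"]).to_csv(path, index=False)


def read_fix_clouds_csv(path) -> list[PosteriorTrack]:
    df = pd.read_csv(path, parse_dates=["time"])
    out = []
    for bird_id, g in df.groupby("bird_id", sort=False):
        fixes = []
        for _, gf in g.groupby("fix", sort=True):
            fixes.append(PrimaryFix(gf["time"].iloc[0], gf["event"].iloc[0],
                                    gf["lon"].to_numpy(), gf["lat"].to_numpy(),
                                    gf["weight"].to_numpy()))
        out.append(PosteriorTrack(str(bird_id), fixes))
    return out


def isopleths_to_geojson(isos, path) -> None:
    from shapely.geometry import mapping
    features = []
    for iso in isos:
        poly = iso.to_polygons()
        if poly is None:
            continue
        features.append({"type": "Feature",
                         "properties": {"population": iso.population,
                                        "level": iso.level,
                                        "mass": iso.mass},
                         "geometry": mapping(poly)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
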