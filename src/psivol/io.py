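"""Readers and writers for the package's on-disk formats.

Populations and estimates are JSON; section rasters are 16-bit labeled TIFFs
with a JSON sidecar carrying the µm-per-pixel scale and origin; profile sets
and cohorts are CSV (the cohort with a JSON schema sidecar); ROIs are GeoJSON
polygons with coordinates in µm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from psivol.errors import ParameterError
from psivol.stereology import ROI, PSIEstimate, SamplingConfig
from psivol.virtual_tissue import Population3D, ProfileSet, SectionImage, SizeDistribution
from psivol.cohort_synth import cohort_columns

__all__ = [
    "save_json", "load_json",
    "save_population", "load_population",
    "save_profiles", "load_profiles",
    "save_section_image", "load_section_image",
    "roi_to_geojson", "roi_from_geojson",
    "save_estimate", "load_sampling_config",
    "save_cohort", "load_cohort",
]


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- population

def save_population(pop: Population3D, path: str | Path) -> None:
    save_json({
        "ids": pop.ids.tolist(),
        "centers": pop.centers.tolist(),
        "radii": pop.radii.tolist(),
        "box": pop.box.tolist(),
        "core": pop.core.tolist(),
        "distribution": pop.distribution.to_dict(),
        "seed": pop.seed,
    }, path)


def load_population(path: str | Path) -> Population3D:
    d = load_json(path)
    return Population3D(
        ids=np.asarray(d["ids"], dtype=int),
        centers=np.asarray(d["centers"], dtype=float),
        radii=np.asarray(d["radii"], dtype=float),
        box=np.asarray(d["box"], dtype=float),
        core=np.asarray(d["core"], dtype=float),
        distribution=SizeDistribution.from_dict(d["distribution"]),
        seed=int(d["seed"]),
    )


# ---------------------------------------------------------------- profiles

def save_profiles(profiles: ProfileSet, path: str | Path) -> None:
    """CSV with columns id, cx, cy, radius; the section height is kept in a
    leading comment line."""
    df = pd.DataFrame({
        "id": profiles.ids,
        "cx": profiles.centers[:, 0] if len(profiles) else [],
        "cy": profiles.centers[:, 1] if len(profiles) else [],
        "radius": profiles.radii,
    })
    with open(path, "w") as fh:
        fh.write(f"# z = {profiles.z}\n")
        df.to_csv(fh, index=False)


def load_profiles(path: str | Path) -> ProfileSet:
    z = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            z = float(first.split("=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return ProfileSet(
        z=z,
        ids=df["id"].to_numpy(dtype=int),
        centers=df[["cx", "cy"]].to_numpy(dtype=float),
        radii=df["radius"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------- raster

def save_section_image(img: SectionImage, path: str | Path) -> None:
    """16-bit labeled TIFF plus ``<path>.json`` sidecar (pixel size, origin)."""
    path = Path(path)
    if img.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ParameterError("label ids exceed 16-bit range")
    tifffile.imwrite(path, img.labels.astype(np.uint16))
    save_json({"pixel_size_um": img.pixel_size, "origin_um": img.origin.tolist()},
              path.with_suffix(path.suffix + ".json"))


def load_section_image(path: str | Path, sidecar: str | Path | None = None) -> SectionImage:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
    meta = load_json(sidecar)
    labels = tifffile.imread(path).astype(np.int32)
    return SectionImage(labels=labels, pixel_size=float(meta["pixel_size_um"]),
                        origin=np.asarray(meta["origin_um"], dtype=float))


# ---------------------------------------------------------------- ROI

def roi_to_geojson(roi: ROI, path: str | Path) -> None:
    ring = [list(v) for v in roi.vertices] + [list(roi.vertices[0])]
    save_json({
        "type": "Feature",
        "properties": {"units": "um"},
        "geometry": {"type": "Polygon", "coordinates": [ring]},
    }, path)


def roi_from_geojson(path: str | Path) -> ROI:
    d = load_json(path)
    geom = d["geometry"] if d.get("type") == "Feature" else d
    if geom.get("type") != "Polygon":
        raise ParameterError("ROI GeoJSON must contain a Polygon geometry")
    ring = geom["coordinates"][0]
    if ring[0] == ring[-1]:
        ring = ring[:-1]
    return ROI(tuple(tuple(map(float, v)) for v in ring))


# ---------------------------------------------------------------- estimates

def save_estimate(est: PSIEstimate, json_path: str | Path,
                  intercepts_csv: str | Path | None = None) -> None:
    """Estimate as JSON; optionally the per-intercept audit table as CSV."""
    save_json({
        "vv_um3": est.vv,
        "n_intercepts": est.n,
        "fields_used": est.fields_used,
        "ce_rel_sem_l3": est.ce,
        "seed": est.seed,
    }, json_path)
    if intercepts_csv is not None:
        rows = [{
            "nucleus_id": i.nucleus_id,
            "length_um": i.length,
            "px": i.point.position[0], "py": i.point.position[1],
            "field_index": i.point.field_index,
            "theta_rad": i.theta,
            "x1": i.endpoints[0, 0], "y1": i.endpoints[0, 1],
            "x2": i.endpoints[1, 0], "y2": i.endpoints[1, 1],
        } for i in est.intercepts]
        pd.DataFrame(rows).to_csv(intercepts_csv, index=False)


def load_sampling_config(path: str | Path) -> SamplingConfig:
    return SamplingConfig.from_dict(load_json(path))


# ---------------------------------------------------------------- cohort

def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    save_json({"columns": cohort_columns()},
              path.with_suffix(path.suffix + ".json"))


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(cohort_columns()) - set(df.columns)
    if missing:
        raise ParameterError(f"cohort table missing columns: {sorted(missing)}")
    return df
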