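"""End-to-end orchestration: simulated tumors → PSI measurement → cohort → statistics.

`simulate_tumor` builds one virtual tumor section (packed sphere population,
section plane through the core, labeled raster, rectangular ROI).  `run_demo`
chains the full workflow for a handful of tumors and writes every artifact
with a manifest of seeds, versions and file hashes, so reruns are verifiably
identical.
"""

from __future__ import annotations

import hashlib
import math
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import psivol
from psivol import io
from psivol.cohort_stats import StatsConfig, run_cohort_pipeline
from psivol.cohort_synth import cohort_to_frame, default_cohort_spec, generate_cohort
from psivol.stereology import ROI, SamplingConfig, replicate_and_average
from psivol.virtual_tissue import (
    Population3D, ProfileSet, SectionImage, SizeDistribution,
    render_profiles, sample_population, section_population, true_vwm_volume,
)

__all__ = ["TissueConfig", "DemoConfig", "simulate_tumor", "lognormal_for_target_vv",
           "run_demo", "SimulatedTumor"]


@dataclass
class TissueConfig:
    """Geometry of one simulated tumor section.

    ``core_xy`` × ``core_xy`` × ``core_z`` µm is the unbiased core region; the
    section plane passes through its mid-height and the ROI is its xy
    footprint.  ``volume_fraction`` is the target sphere packing fraction —
    a free simulator parameter (real tumor cellularity is not characterized),
    defaulting to a dense but reliably packable 0.15.
    """

    core_xy: float = 300.0
    core_z: float = 20.0
    volume_fraction: float = 0.15
    pixel_size: float = 0.25  # µm/pixel, finer than any relevant profile

    def count_for(self, dist: SizeDistribution) -> int:
        mean_vol = 4.0 * math.pi / 3.0 * dist.radius_moment(3)
        # rmax is unknown before sampling; a generous bound inflates the box estimate
        rmax = _radius_bound(dist)
        vol = (self.core_xy + 4 * rmax) ** 2 * (self.core_z + 4 * rmax)
        return max(1, int(round(self.volume_fraction * vol / mean_vol)))


def _radius_bound(dist: SizeDistribution) -> float:
    if dist.family == "monodisperse":
        return dist.radius
    if dist.family == "two_point":
        return max(dist.r1, dist.r2)
    return math.exp(dist.mu + 3.5 * dist.sigma)


def lognormal_for_target_vv(target_vv: float, sigma: float = 0.15) -> SizeDistribution:
    """Lognormal radius law whose volume-weighted mean volume equals ``target_vv`` µm³.

    For ln R ~ N(µ, σ²): v̄v = (4π/3)·exp(3µ + 13.5σ²), inverted for µ.
    """
    mu = (math.log(3.0 * target_vv / (4.0 * math.pi)) - 13.5 * sigma**2) / 3.0
    return SizeDistribution("lognormal", mu=mu, sigma=sigma)


@dataclass
class SimulatedTumor:
    population: Population3D
    profiles: ProfileSet
    image: SectionImage
    roi: ROI
    true_vv: float


def simulate_tumor(
    dist: SizeDistribution,
    seed: int,
    tissue: TissueConfig | None = None,
    render: bool = True,
) -> SimulatedTumor:
    """Pack, section and (optionally) rasterize one virtual tumor."""
    cfg = tissue or TissueConfig()
    half = cfg.core_xy / 2.0
    core = [[-half, -half, -cfg.core_z / 2.0], [half, half, cfg.core_z / 2.0]]
    pop = sample_population(dist, cfg.count_for(dist), core, seed=seed)
    profiles = section_population(pop, z=0.0)
    roi = ROI.rectangle(-half, -half, half, half)
    img = None
    if render:
        # render the full inflated footprint so chords starting near the ROI
        # edge are never truncated at the raster border
        img = render_profiles(profiles, cfg.pixel_size, bounds=pop.box[:, :2])
    return SimulatedTumor(pop, profiles, img, roi, true_vwm_volume(dist))


@dataclass
class DemoConfig:
    """Small but complete end-to-end run: 3 tumors per grade, 4 replicates each."""

    seed: int = 0
    n_per_grade: int = 3
    target_vv: tuple[float, float] = (115.1, 196.8)  # per-grade v̄v targets, µm³
    tissue: TissueConfig = field(default_factory=lambda: TissueConfig(
        core_xy=300.0, core_z=20.0, pixel_size=0.4))
    sampling: SamplingConfig = field(default_factory=lambda: SamplingConfig(
        point_spacing=math.sqrt(10300.84) / 8.0))
    cohort_n: int = 55


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(outdir: str | Path, config: DemoConfig | None = None) -> dict:
    """Run the full workflow and write artifacts plus a manifest.

    Produces, under ``outdir``: per-tumor population JSON, section TIFF +
    sidecar, profile CSV, replicate estimate JSONs; a cohort CSV; the cohort
    statistics report; and ``manifest.json`` recording the package version,
    every seed, per-stage status and the SHA-256 of every artifact.  Failed
    stages are recorded rather than aborting the rest.
    """
    cfg = config or DemoConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "psivol",
        "version": psivol.__version__,
        "seed": cfg.seed,
        "stages": {},
        "artifacts": {},
    }
    root_rng = np.random.default_rng(cfg.seed)
    tumor_seeds = root_rng.integers(0, 2**31 - 1, size=cfg.n_per_grade * 2)
    replicate_offsets = (11, 23, 37, 51)

    tumors = []
    try:
        for t, target in enumerate(cfg.target_vv):
            dist = lognormal_for_target_vv(target)
            for k in range(cfg.n_per_grade):
                idx = t * cfg.n_per_grade + k
                seed = int(tumor_seeds[idx])
                sim = simulate_tumor(dist, seed, cfg.tissue)
                stem = out / f"tumor_{idx:02d}"
                io.save_population(sim.population, f"{stem}_population.json")
                io.save_profiles(sim.profiles, f"{stem}_profiles.csv")
                io.save_section_image(sim.image, f"{stem}_section.tif")
                io.roi_to_geojson(sim.roi, f"{stem}_roi.geojson")
                rep = replicate_and_average(
                    sim.image, sim.roi, cfg.sampling,
                    seeds=[seed + o for o in replicate_offsets])
                for j, est in enumerate(rep.estimates):
                    io.save_estimate(est, f"{stem}_estimate_rep{j}.json")
                io.save_json({"vv_avg_um3": rep.average,
                              "replicates": rep.values.tolist(),
                              "true_vv_um3": sim.true_vv,
                              "seed": seed}, f"{stem}_vv.json")
                tumors.append({"tumor": idx, "seed": seed, "true_vv": sim.true_vv,
                               "vv_avg": rep.average})
        manifest["stages"]["measure"] = {"status": "ok", "tumors": tumors}
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["measure"] = {"status": "failed",
                                         "error": f"{type(exc).__name__}: {exc}"}

    cohort_seed = int(root_rng.integers(0, 2**31 - 1))
    try:
        spec = default_cohort_spec(seed=cohort_seed)
        spec.n_cases = cfg.cohort_n
        df = cohort_to_frame(generate_cohort(spec))
        io.save_cohort(df, out / "cohort.csv")
        manifest["stages"]["cohort"] = {"status": "ok", "seed": cohort_seed,
                                        "n_cases": len(df)}
        report = run_cohort_pipeline(df, StatsConfig())
        io.save_json(report, out / "stats_report.json")
        failed = [k for k, v in report.items()
                  if isinstance(v, dict) and v.get("status") == "failed"]
        manifest["stages"]["stats"] = {"status": "ok" if not failed else "partial",
                                       "failed_stages": failed}
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["stats"] = {"status": "failed",
                                       "error": f"{type(exc).__name__}: {exc}"}

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _sha256(p)
    manifest["ok"] = all(s.get("status") in ("ok", "partial")
                         for s in manifest["stages"].values())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
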