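"""Simulated 3D nuclear populations with analytically known volume-weighted mean volume.

Nuclei are modeled as non-overlapping spheres.  For spheres the point-sampled
intercept estimator is unbiased under any section orientation, so a population
drawn from a size law with closed-form moments is an exact oracle for the
measurement engine: the estimator's expectation is (4π/3)·E[R⁶]/E[R³],
computable in closed form for every supported size family.

The sampling box is inflated by twice the largest radius in every direction
and the guaranteed-unbiased *core* region is tracked separately: sectioning
planes and ROIs restricted to the core see a stationary sphere process that is
complete out to the full reach of any measurable chord, so edge truncation
cannot bias profile sizes or intercept lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from psivol.errors import ParameterError, PackingError

__all__ = [
    "SizeDistribution", "Nucleus3D", "Population3D", "ProfileSet", "SectionImage",
    "sample_population", "true_vwm_volume", "true_number_mean_volume",
    "section_population", "render_profiles",
]

_SPHERE = 4.0 * math.pi / 3.0


@dataclass(frozen=True)
class SizeDistribution:
    """Radius law of a spherical nuclear population.

    Families
    --------
    ``monodisperse``
        every radius equals ``radius`` (µm).
    ``lognormal``
        ln R ~ Normal(``mu``, ``sigma``) with R in µm.
    ``two_point``
        R = ``r1`` with probability ``weight``, else ``r2``.
    """

    family: Literal["monodisperse", "lognormal", "two_point"]
    radius: float | None = None
    mu: float | None = None
    sigma: float | None = None
    r1: float | None = None
    r2: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.family == "monodisperse":
            if self.radius is None or self.radius <= 0:
                raise ParameterError("monodisperse radius must be > 0")
        elif self.family == "lognormal":
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ParameterError("lognormal requires mu and sigma > 0")
        elif self.family == "two_point":
            if (
                self.r1 is None or self.r2 is None or self.weight is None
                or self.r1 <= 0 or self.r2 <= 0 or not (0.0 < self.weight < 1.0)
            ):
                raise ParameterError("two_point requires r1, r2 > 0 and weight in (0, 1)")
        else:
            raise ParameterError(f"unknown size family {self.family!r}")

    def radius_moment(self, k: int) -> float:
        """E[R^k] in µm^k, in closed form."""
        if self.family == "monodisperse":
            return self.radius ** k
        if self.family == "lognormal":
            return math.exp(k * self.mu + 0.5 * k * k * self.sigma**2)
        return self.weight * self.r1**k + (1.0 - self.weight) * self.r2**k

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. radii (µm)."""
        if self.family == "monodisperse":
            return np.full(n, float(self.radius))
        if self.family == "lognormal":
            return np.exp(rng.normal(self.mu, self.sigma, size=n))
        picks = rng.random(n) < self.weight
        return np.where(picks, self.r1, self.r2).astype(float)

    def to_dict(self) -> dict:
        d = {"family": self.family}
        for k in ("radius", "mu", "sigma", "r1", "r2", "weight"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SizeDistribution":
        return cls(**d)


@dataclass(frozen=True)
class Nucleus3D:
    id: int
    center: np.ndarray  # (3,) µm
    radius: float  # µm


@dataclass
class Population3D:
    """A packed spherical population.

    ``box`` is the full sampling box (every center lies inside it); ``core`` is
    the sub-box over which sectioning is free of edge-truncation bias.
    """

    ids: np.ndarray  # (n,) int
    centers: np.ndarray  # (n, 3) µm
    radii: np.ndarray  # (n,) µm
    box: np.ndarray  # (2, 3) [[lo], [hi]] µm
    core: np.ndarray  # (2, 3) µm
    distribution: SizeDistribution
    seed: int

    def __len__(self) -> int:
        return self.ids.size

    @property
    def nuclei(self) -> list[Nucleus3D]:
        return [
            Nucleus3D(int(i), c, float(r))
            for i, c, r in zip(self.ids, self.centers, self.radii)
        ]


@dataclass
class ProfileSet:
    """Circular profiles produced by one section plane (vector form)."""

    z: float  # µm
    ids: np.ndarray  # (m,) parent nucleus ids
    centers: np.ndarray  # (m, 2) µm
    radii: np.ndarray  # (m,) disc radii µm

    def __len__(self) -> int:
        return self.ids.size


@dataclass
class SectionImage:
    """Labeled raster of a section: 0 = background, k = nucleus id."""

    labels: np.ndarray  # (ny, nx) int32
    pixel_size: float  # µm / pixel
    origin: np.ndarray  # (2,) µm position of the top-left pixel corner

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in µm."""
        ny, nx = self.labels.shape
        x0, y0 = float(self.origin[0]), float(self.origin[1])
        return x0, y0, x0 + nx * self.pixel_size, y0 + ny * self.pixel_size

    def label_at(self, x: float, y: float) -> int:
        """Label of the pixel whose area contains the point (x, y) µm.

        Points exactly on a pixel boundary belong to the pixel on the
        higher-index side (floor convention); outside the raster is background.
        """
        ix = int(math.floor((x - self.origin[0]) / self.pixel_size))
        iy = int(math.floor((y - self.origin[1]) / self.pixel_size))
        ny, nx = self.labels.shape
        if 0 <= ix < nx and 0 <= iy < ny:
            return int(self.labels[iy, ix])
        return 0


def true_vwm_volume(dist: SizeDistribution) -> float:
    """Volume-weighted mean sphere volume E[V²]/E[V] = (4π/3)·E[R⁶]/E[R³] (µm³)."""
    return _SPHERE * dist.radius_moment(6) / dist.radius_moment(3)


def true_number_mean_volume(dist: SizeDistribution) -> float:
    """Ordinary (number-weighted) mean sphere volume (4π/3)·E[R³] (µm³)."""
    return _SPHERE * dist.radius_moment(3)


def sample_population(
    dist: SizeDistribution,
    count: int,
    box: np.ndarray | list,
    seed: int,
    max_attempts: int = 500,
) -> Population3D:
    """Pack ``count`` non-overlapping spheres with centers uniform over an inflated box.

    Parameters
    ----------
    box
        ``[[xlo, ylo, zlo], [xhi, yhi, zhi]]`` in µm — the *core* region.  The
        actual center-sampling box is inflated by twice the largest sampled
        radius on every side, so that sections and ROIs inside the core are
        unbiased and chords never leave the rendered geometry.
    max_attempts
        rejection-sampling attempts per sphere before giving up with a
        :class:`~psivol.errors.PackingError` (never silent under-filling).
    """
    if count < 1:
        raise ParameterError("count must be >= 1")
    core = np.asarray(box, dtype=float).reshape(2, 3)
    if np.any(core[1] <= core[0]):
        raise ParameterError("box must be nondegenerate (hi > lo on every axis)")
    rng = np.random.default_rng(seed)
    radii = dist.sample(count, rng)
    rmax = float(radii.max())
    # inflate by 2·rmax: every disc that can contain an ROI point, and the full
    # extent of every chord through such a point, lies inside the box
    lo = core[0] - 2.0 * rmax
    hi = core[1] + 2.0 * rmax
    span = hi - lo

    # Hard-sphere rejection sampling with *periodic* (minimum-image) overlap
    # tests.  A hard wall would segregate sphere sizes near the boundary (large
    # spheres see more free volume there), biasing the composition seen by the
    # section plane; on the torus the packed process is exactly stationary.
    ncell = np.maximum(1, (span // (2.0 * rmax)).astype(int))
    cell = span / ncell
    grid: dict[tuple[int, int, int], list[int]] = {}
    centers = np.empty((count, 3))

    def _key(c: np.ndarray) -> tuple[int, int, int]:
        k = np.minimum(((c - lo) / cell).astype(int), ncell - 1)
        return (int(k[0]), int(k[1]), int(k[2]))

    for i in range(count):
        r = radii[i]
        for _ in range(max_attempts):
            c = lo + rng.random(3) * span
            kx, ky, kz = _key(c)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        key = ((kx + dx) % ncell[0], (ky + dy) % ncell[1],
                               (kz + dz) % ncell[2])
                        for j in grid.get(key, ()):
                            d = c - centers[j]
                            d -= span * np.round(d / span)  # minimum image
                            s = r + radii[j]
                            if d @ d < s * s:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers[i] = c
                grid.setdefault((kx, ky, kz), []).append(i)
                break
        else:
            raise PackingError(count, i, max_attempts)

    return Population3D(
        ids=np.arange(1, count + 1),
        centers=centers,
        radii=radii,
        box=np.stack([lo, hi]),
        core=core,
        distribution=dist,
        seed=seed,
    )


def section_population(pop: Population3D, z: float) -> ProfileSet:
    """Cut the population with the plane at height ``z`` (µm).

    Nucleus *i* yields a disc iff ``|z - z_i| < r_i``; the disc has radius
    ``sqrt(r_i² - (z - z_i)²)`` centered at ``(x_i, y_i)``.  Disjoint spheres
    always yield disjoint discs.
    """
    if not (pop.box[0, 2] <= z <= pop.box[1, 2]):
        raise ParameterError(f"section plane z={z} outside population box")
    dz = z - pop.centers[:, 2]
    hit = np.abs(dz) < pop.radii
    rho = np.sqrt(pop.radii[hit] ** 2 - dz[hit] ** 2)
    return ProfileSet(
        z=float(z),
        ids=pop.ids[hit].copy(),
        centers=pop.centers[hit, :2].copy(),
        radii=rho,
    )


def render_profiles(
    profiles: ProfileSet,
    pixel_size: float,
    bounds: np.ndarray | list | None = None,
) -> SectionImage:
    """Rasterize discs onto a labeled grid.

    A pixel gets label *k* iff its center lies inside disc *k*; where discs
    overlap the pixel goes to the disc whose center is closest.  ``bounds``
    (``[[xlo, ylo], [xhi, yhi]]`` µm) defaults to the discs' bounding box.  A
    disc so small that no pixel center falls inside it is left unrendered with
    a warning.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be > 0")
    if bounds is None:
        if len(profiles) == 0:
            bounds = np.array([[0.0, 0.0], [1.0, 1.0]])
        else:
            lo = (profiles.centers - profiles.radii[:, None]).min(axis=0)
            hi = (profiles.centers + profiles.radii[:, None]).max(axis=0)
            bounds = np.stack([lo, hi])
    bounds = np.asarray(bounds, dtype=float).reshape(2, 2)
    origin = bounds[0]
    nx = max(1, int(math.ceil((bounds[1, 0] - bounds[0, 0]) / pixel_size)))
    ny = max(1, int(math.ceil((bounds[1, 1] - bounds[0, 1]) / pixel_size)))
    labels = np.zeros((ny, nx), dtype=np.int32)
    best_d2 = np.full((ny, nx), np.inf)

    for k in range(len(profiles)):
        cx, cy = profiles.centers[k]
        rho = profiles.radii[k]
        fully_inside = (
            bounds[0, 0] <= cx - rho and cx + rho <= bounds[1, 0]
            and bounds[0, 1] <= cy - rho and cy + rho <= bounds[1, 1]
        )
        ix0 = max(0, int(math.floor((cx - rho - origin[0]) / pixel_size)))
        ix1 = min(nx, int(math.ceil((cx + rho - origin[0]) / pixel_size)) + 1)
        iy0 = max(0, int(math.floor((cy - rho - origin[1]) / pixel_size)))
        iy1 = min(ny, int(math.ceil((cy + rho - origin[1]) / pixel_size)) + 1)
        if ix0 >= ix1 or iy0 >= iy1:
            continue  # disc outside the raster window: clipped, not an error
        xs = origin[0] + (np.arange(ix0, ix1) + 0.5) * pixel_size
        ys = origin[1] + (np.arange(iy0, iy1) + 0.5) * pixel_size
        dx2 = (xs - cx) ** 2
        dy2 = (ys - cy) ** 2
        d2 = dy2[:, None] + dx2[None, :]
        inside = d2 < rho * rho
        if not inside.any():
            if fully_inside:
                warnings.warn(
                    f"disc {int(profiles.ids[k])} (radius {rho:.3g} µm) covers no pixel "
                    f"at pixel size {pixel_size:g} µm; unrendered"
                )
            continue
        sub_lab = labels[iy0:iy1, ix0:ix1]
        sub_d2 = best_d2[iy0:iy1, ix0:ix1]
        take = inside & (d2 < sub_d2)
        sub_lab[take] = profiles.ids[k]
        sub_d2[take] = d2[take]

    return SectionImage(labels=labels, pixel_size=float(pixel_size), origin=origin.copy())
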