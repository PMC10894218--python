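"""Synthetic census landscapes with urban-core structure.

Real block-level census tessellations mix small, dense urban polygons
with large, sparse rural ones, include unpopulated units, and show a
clear anticorrelation between unit area and population density.  This
module generates seeded synthetic landscapes with those properties so
the aggregation simulator and everything downstream can be exercised
end-to-end without any deposited data.

Construction: seed points are drawn from a mixture of Gaussian urban
cores plus a uniform rural background; the Voronoi tessellation of the
points (clipped to a square extent) gives the units, so cells are small
where points cluster.  Population is a smooth core-peaked density
surface evaluated at each cell, times cell area, times multiplicative
lognormal noise; the largest units are zeroed by quota and the rest are
rescaled to the target total with largest-remainder rounding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import yaml
from scipy import stats
from shapely import STRtree
from shapely.geometry import MultiPoint, box

from .landscape import AreaUnit, Tessellation, M2_PER_KM2

__all__ = [
    "LandscapeSpec",
    "GenerationError",
    "generate_landscape",
    "area_density_correlation",
]

#: Minimum seed-point spacing in metres; two generator points closer than
#: this are redrawn so Voronoi cells stay non-degenerate.
MIN_SPACING_M = 1.0

#: Share of seed points drawn from the urban cores (vs uniform background).
#: High by design: in block-level census tessellations the large majority
#: of units are small urban blocks.
URBAN_FRACTION = 0.9

#: Density-surface shape: peak amplitude of each core relative to the
#: rural floor.  Absolute scale is irrelevant (populations are rescaled).
CORE_AMPLITUDE = 200.0
FLOOR_DENSITY = 1.0


class GenerationError(ValueError):
    """Raised when a spec cannot be realised (e.g. extent too crowded)."""


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of one synthetic landscape.

    Attributes
    ----------
    n_units : int
        Number of areal units (Voronoi cells), >= 2.
    extent_km : float
        Side length of the square study area, km.
    n_cores : int
        Number of Gaussian urban cores.
    core_sd_km : float
        Spatial spread (standard deviation) of each core, km.
    zero_pop_fraction : float
        Fraction of units set to population zero (largest units first).
    total_pop : int
        Target total persons; met exactly up to rounding.
    density_noise_sd : float
        Standard deviation of the lognormal noise on log density.
    urban_fraction : float
        Share of units seeded inside cores rather than uniformly.
    seed : int
        RNG seed; the full landscape is a deterministic function of it.
    """

    n_units: int = 1000
    extent_km: float = 30.0
    n_cores: int = 3
    core_sd_km: float = 1.2
    zero_pop_fraction: float = 0.08
    total_pop: int = 500_000
    density_noise_sd: float = 0.5
    urban_fraction: float = URBAN_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if not 0 <= self.zero_pop_fraction < 1:
            raise ValueError("zero_pop_fraction must be in [0, 1)")
        if self.total_pop < 0:
            raise ValueError("total_pop must be >= 0")
        if self.extent_km <= 0 or self.core_sd_km <= 0:
            raise ValueError("extent_km and core_sd_km must be positive")

    # Flat key-value round-trip (YAML) so specs can live in config files.
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


def generate_landscape(spec: LandscapeSpec) -> Tessellation:
    """Realise a :class:`LandscapeSpec` as a valid :class:`Tessellation`.

    Deterministic per seed: all stochastic choices draw from a single
    ``numpy`` Generator in a fixed order (core centres, seed points,
    population noise).
    """
    side_m = spec.extent_km * 1000.0
    if spec.n_units * (2.0 * MIN_SPACING_M) ** 2 > side_m * side_m:
        raise GenerationError(
            f"extent of {spec.extent_km} km cannot host {spec.n_units} units "
            f"at {MIN_SPACING_M} m minimum spacing"
        )
    rng = np.random.default_rng(spec.seed)
    extent = box(0.0, 0.0, side_m, side_m)

    # Core centres sit in the central 60% of the extent.
    lo, hi = 0.2 * side_m, 0.8 * side_m
    cores = rng.uniform(lo, hi, size=(spec.n_cores, 2))
    sd_m = spec.core_sd_km * 1000.0

    pts = _draw_points(rng, spec, cores, sd_m, side_m)
    cells = _voronoi_cells(pts, extent)

    areas_km2 = shapely.area(np.asarray(cells, dtype=object)) / M2_PER_KM2
    centroids = shapely.centroid(np.asarray(cells, dtype=object))
    cx = shapely.get_x(centroids)
    cy = shapely.get_y(centroids)

    dens = _density_surface(cx, cy, cores, sd_m)
    noise = rng.lognormal(mean=0.0, sigma=spec.density_noise_sd,
                          size=spec.n_units)
    raw = dens * areas_km2 * noise

    # Zero-population quota on the largest units, then exact rescale.
    n_zero = int(round(spec.zero_pop_fraction * spec.n_units))
    order = np.argsort(areas_km2)
    zero_idx = order[::-1][:n_zero]
    raw[zero_idx] = 0.0
    pops = _rescale_to_total(raw, spec.total_pop)

    units = [
        AreaUnit.from_geometry(uid, cells[uid], int(pops[uid]))
        for uid in range(spec.n_units)
    ]
    return Tessellation.from_units(units, crs=None, extent=extent)


def area_density_correlation(tess: Tessellation) -> float:
    """Spearman rank correlation between unit area and population density.

    Requires at least 3 units and two distinct values of each variable;
    a constant input has no defined rank correlation.
    """
    areas = tess.areas()
    dens = tess.densities()
    if len(areas) < 3:
        raise ValueError("need at least 3 units")
    if np.unique(dens).size < 2 or np.unique(areas).size < 2:
        raise ValueError("correlation undefined for constant input")
    rho, _ = stats.spearmanr(areas, dens)
    return float(rho)


# ---------------------------------------------------------------------------

def _draw_points(rng, spec, cores, sd_m, side_m):
    """Mixture draw: urban (Gaussian around cores) + rural (uniform)."""
    n_urban = int(round(spec.urban_fraction * spec.n_units))
    coords = np.empty((spec.n_units, 2))
    which = rng.integers(0, spec.n_cores, size=n_urban)
    for i in range(n_urban):
        for _ in range(1000):
            p = rng.normal(cores[which[i]], sd_m)
            if 0.0 < p[0] < side_m and 0.0 < p[1] < side_m:
                coords[i] = p
                break
        else:
            raise GenerationError("could not place an urban point inside extent")
    coords[n_urban:] = rng.uniform(0.0, side_m, size=(spec.n_units - n_urban, 2))

    # Enforce minimum spacing by redrawing offenders uniformly.
    for _ in range(100):
        tree = shapely.STRtree(shapely.points(coords))
        pairs = tree.query(shapely.points(coords), predicate="dwithin",
                           distance=MIN_SPACING_M)
        bad = np.unique(pairs[1][pairs[0] < pairs[1]])
        if bad.size == 0:
            return coords
        coords[bad] = rng.uniform(0.0, side_m, size=(bad.size, 2))
    raise GenerationError("could not satisfy minimum point spacing")


def _voronoi_cells(coords, extent):
    """Voronoi polygons of the points, clipped to extent, in point order."""
    pt_geoms = shapely.points(coords)
    raw = shapely.voronoi_polygons(MultiPoint(list(pt_geoms)), extend_to=extent)
    tree = STRtree(list(pt_geoms))
    cells = [None] * len(coords)
    for cell in raw.geoms:
        hit = tree.query(cell, predicate="covers")
        if len(hit):
            cells[int(hit[0])] = shapely.intersection(cell, extent)
    if any(c is None or c.is_empty for c in cells):
        raise GenerationError("degenerate Voronoi cell; adjust spec")
    return cells


def _density_surface(x, y, cores, sd_m):
    """Smooth persons/km² surface: Gaussian bumps at cores + rural floor."""
    d = np.full_like(x, FLOOR_DENSITY, dtype=float)
    for cx, cy in cores:
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        d += CORE_AMPLITUDE * np.exp(-r2 / (2.0 * sd_m**2))
    return d


def _rescale_to_total(raw: np.ndarray, total: int) -> np.ndarray:
    """Scale non-negative reals to integers summing exactly to ``total``.

    Largest-remainder rounding; all-zero input puts the whole total on
    index 0 (degenerate but conserving).
    """
    raw = np.asarray(raw, dtype=float)
    s = raw.sum()
    if s <= 0:
        out = np.zeros(len(raw), dtype=np.int64)
        if total > 0:
            out[0] = total
        return out
    scaled = raw * (total / s)
    base = np.floor(scaled).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        remainders = scaled - base
        top = np.argsort(remainders)[::-1][:short]
        base[top] += 1
    return base
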