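"""Mass-preserving dasymetric disaggregation of unit counts to a grid.

Each areal unit's population count is redistributed over the pixels
whose centres fall inside it, proportionally to a supplied weight raster
(or uniformly).  The redistribution conserves mass exactly: per-unit
pixel sums equal the unit count, and the raster total equals the
tessellation total.  The weight raster is a pluggable interface — any
externally produced non-negative surface (e.g. from a random-forest
weighting model) can be passed in; this module never trains one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import shapely

from . import metrics
from .grids import GridSpec, PopulationRaster, Raster, WeightRaster
from .landscape import Tessellation

__all__ = [
    "assign_pixels",
    "redistribute",
    "compare_realizations",
    "RedistributionReport",
    "ComparisonResult",
]


def assign_pixels(tess: Tessellation, grid: GridSpec) -> np.ndarray:
    """Map each pixel to the uid of the unit containing its centre.

    Returns an int array of shape ``grid.shape``; pixels whose centre
    lies outside every unit get -1 (nodata).  A centre exactly on a
    shared edge goes to the lower uid.
    """
    if tess.crs is not None and grid.crs is not None and tess.crs != grid.crs:
        raise ValueError(f"CRS mismatch: tessellation {tess.crs}, grid {grid.crs}")
    x, y = grid.pixel_centers()
    out = np.full(grid.shape, -1, dtype=np.int64)
    ps = grid.pixel_size
    for uid in sorted(tess.units):  # ascending: lower uid wins edge ties
        geom = tess.units[uid].geometry
        minx, miny, maxx, maxy = geom.bounds
        cols = np.nonzero((x[0] >= minx - ps) & (x[0] <= maxx + ps))[0]
        rows = np.nonzero((y[:, 0] >= miny - ps) & (y[:, 0] <= maxy + ps))[0]
        if cols.size == 0 or rows.size == 0:
            continue
        sub = np.ix_(rows, cols)
        hit = shapely.intersects_xy(geom, x[sub], y[sub])
        free = out[sub] == -1
        block = out[sub]
        block[hit & free] = uid
        out[sub] = block
    return out


@dataclass
class RedistributionReport:
    """Bookkeeping of a redistribution run.

    ``pixelless_units`` received their whole count on the single pixel
    nearest their centroid (they covered no pixel centre); ``donations``
    records that pixel per such unit (its value therefore exceeds the
    owning unit's share); ``zero_weight_units`` had all-zero weights and
    fell back to uniform.
    """

    pixelless_units: list[int] = field(default_factory=list)
    zero_weight_units: list[int] = field(default_factory=list)
    donations: dict[int, tuple[int, int]] = field(default_factory=dict)


def redistribute(
    tess: Tessellation,
    grid: GridSpec,
    weights: WeightRaster | Literal["uniform"] = "uniform",
) -> tuple[PopulationRaster, RedistributionReport]:
    """Disaggregate unit counts to people-per-pixel, conserving mass.

    Within each unit, pixel value = unit pop × weight / (sum of weights
    over the unit's pixels); ``"uniform"`` gives equal shares.  Units
    with all-zero weights fall back to uniform (recorded); units whose
    geometry captures no pixel centre put their whole count on the pixel
    nearest their centroid so no mass is ever dropped.
    """
    if isinstance(weights, WeightRaster) and not weights.grid.matches(grid):
        raise ValueError("weight raster is not aligned to the target grid")
    assignment = assign_pixels(tess, grid)
    w = (
        np.ones(grid.shape, dtype=float)
        if isinstance(weights, str)
        else weights.values.copy()
    )
    values = np.zeros(grid.shape, dtype=float)
    report = RedistributionReport()
    x, y = grid.pixel_centers()
    for uid, unit in tess.units.items():
        mask = assignment == uid
        if not mask.any():
            report.pixelless_units.append(uid)
            c = unit.geometry.centroid
            idx = np.unravel_index(
                np.argmin((x - c.x) ** 2 + (y - c.y) ** 2), grid.shape
            )
            values[idx] += unit.pop
            report.donations[uid] = (int(idx[0]), int(idx[1]))
            continue
        wu = w[mask]
        total_w = wu.sum()
        if total_w <= 0:
            report.zero_weight_units.append(uid)
            wu = np.ones_like(wu)
            total_w = wu.sum()
        values[mask] += unit.pop * wu / total_w
    nodata = (assignment == -1) & (values == 0)
    return PopulationRaster(grid=grid, values=values, nodata_mask=nodata), report


@dataclass
class ComparisonResult:
    """Disaggregated realisations plus their pairwise and pooled comparisons."""

    rasters: dict[tuple[int, int], PopulationRaster]
    ndpi: dict[tuple[tuple[int, int], tuple[int, int]], Raster]
    lower: dict[int, np.ndarray]
    upper: dict[int, np.ndarray]
    ess: dict[int, np.ndarray]


def compare_realizations(
    archive,
    grid: GridSpec,
    weights: WeightRaster | Literal["uniform"] = "uniform",
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] | None = None,
    alpha: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
) -> ComparisonResult:
    """Disaggregate every (seed, level) realisation of an archive on one
    grid, compute NDPI for the requested realisation pairs, and bootstrap
    per-pixel intervals across seeds at each level.

    ``archive`` is a :class:`~maupsim.aggregator.SimulationArchive` or a
    mapping ``(seed, target) -> Tessellation``.
    """
    realizations = _as_realization_map(archive)
    if len(realizations) < 2:
        raise ValueError("need at least 2 (seed, level) realizations")
    rasters = {
        key: redistribute(tess, grid, weights)[0]
        for key, tess in realizations.items()
    }
    if pairs is None:
        keys = sorted(rasters)
        pairs = [(keys[0], keys[1])]
    ndpi_maps = {(a, b): metrics.ndpi(rasters[a], rasters[b]) for a, b in pairs}
    lower: dict[int, np.ndarray] = {}
    upper: dict[int, np.ndarray] = {}
    ess: dict[int, np.ndarray] = {}
    by_level: dict[int, list[np.ndarray]] = {}
    for (s, t), raster in rasters.items():
        by_level.setdefault(t, []).append(raster.values)
    for level, stack in by_level.items():
        if len(stack) < 2:
            continue
        lo, up, n_eff = metrics.bootstrap_interval(
            np.stack(stack), alpha=alpha, n_boot=n_boot, seed=seed
        )
        lower[level], upper[level], ess[level] = lo, up, n_eff
    return ComparisonResult(
        rasters=rasters, ndpi=ndpi_maps, lower=lower, upper=upper, ess=ess
    )


def _as_realization_map(archive) -> Mapping[tuple[int, int], Tessellation]:
    if hasattr(archive, "results"):
        return {key: tess for key, (tess, _) in archive.results.items()}
    return dict(archive)
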