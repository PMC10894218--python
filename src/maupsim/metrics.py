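"""Evaluation statistics over simulation archives and population grids.

Covers the average spatial resolution (ASR) of a tessellation, pooled
log-scale distribution summaries across the seeds of a level, per-unit
merge frequency across simulations, the Normalised Difference Population
Index (NDPI) between two population rasters, and non-parametric
bootstrap intervals across realisations.

NDPI compares two people-per-pixel surfaces A and B as::

    NDPI = (A - B) / (A + B)

per pixel, bounded in [-1, 1] for non-negative inputs; like NDVI it
weights differences at low and high magnitudes equally.  Pixels where
both surfaces are zero are set to 0 (the surfaces agree nobody lives
there).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .aggregator import MergeLog, SimulationArchive
from .grids import GridAlignmentError, PopulationRaster, Raster
from .landscape import Tessellation

__all__ = [
    "DistributionSummary",
    "asr",
    "summarize_distributions",
    "unit_merge_frequency",
    "ndpi",
    "bootstrap_interval",
]


def asr(tess: Tessellation) -> float:
    """Average spatial resolution: sqrt of mean unit area, in km.

    A single length summarising the coarseness of a tessellation, as
    used for population grids.
    """
    if tess.n_units == 0:
        raise ValueError("ASR undefined for an empty tessellation")
    return float(np.sqrt(tess.areas().mean()))


@dataclass(frozen=True)
class DistributionSummary:
    """Log-scale summary of one variable at one level, pooled over seeds.

    Natural-log scale; ``n_excluded`` counts zero values dropped before
    the log transform (only relevant for pop and density).
    """

    level: int
    variable: str
    median: float
    mean: float
    p2_5: float
    p97_5: float
    n: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.p2_5 <= self.median <= self.p97_5):
            raise ValueError("percentile ordering violated")


_VARIABLES = ("area", "pop", "density")


def summarize_distributions(
    archive: SimulationArchive | Mapping[int, Tessellation], level: int
) -> dict[str, DistributionSummary]:
    """Pooled log-scale summaries of area, pop and density at a level.

    Values are pooled over the units of every seed's tessellation at
    ``level``, log-transformed (natural log), with zero populations
    excluded from the pop and density summaries (their count is
    reported).  Raises if a variable is all zero.
    """
    if isinstance(archive, SimulationArchive):
        tessellations = archive.level_tessellations(level)
    else:
        tessellations = dict(archive)
    if not tessellations:
        raise ValueError(f"no seed present at level {level}")
    pooled = {v: [] for v in _VARIABLES}
    for tess in tessellations.values():
        pooled["area"].append(tess.areas())
        pooled["pop"].append(tess.pops().astype(float))
        pooled["density"].append(tess.densities())
    out: dict[str, DistributionSummary] = {}
    for var in _VARIABLES:
        values = np.concatenate(pooled[var])
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError(f"all values of {var!r} are zero at level {level}")
        logs = np.log(positive)
        # empirical (inverted-CDF) quantiles: invariant under pooling
        # identical seeds, unlike interpolated quantiles
        out[var] = DistributionSummary(
            level=level,
            variable=var,
            median=float(np.percentile(logs, 50, method="inverted_cdf")),
            mean=float(np.mean(logs)),
            p2_5=float(np.percentile(logs, 2.5, method="inverted_cdf")),
            p97_5=float(np.percentile(logs, 97.5, method="inverted_cdf")),
            n=int(positive.size),
            n_excluded=int(values.size - positive.size),
        )
    return out


def unit_merge_frequency(
    logs: Mapping[int, MergeLog], base: Tessellation, level: int
) -> pd.DataFrame:
    """How many seeds merged each original unit by the time ``level`` was
    reached.

    For each base uid, counts the seeds whose chain log down to ``level``
    contains the uid as either the merged or the absorbing unit.  The
    result (indexed by uid, one ``count`` column) can be joined to the
    base geometry for choropleth export.
    """
    counts = pd.Series(0, index=pd.Index(base.uids, name="uid"), dtype=int)
    for seed, log in logs.items():
        upto = log.upto(level)
        if not any(e.target == level for e in upto.events):
            raise ValueError(f"level {level} absent from log of seed {seed}")
        touched: set[int] = set()
        for e in upto.events:
            touched.add(e.merged_uid)
            touched.add(e.into_uid)
        counts.loc[sorted(touched & set(counts.index))] += 1
    return counts.to_frame("count")


def ndpi(a: PopulationRaster, b: PopulationRaster) -> Raster:
    """Per-pixel Normalised Difference Population Index of two rasters.

    Both rasters must share the grid spec exactly.  0/0 pixels map to 0;
    nodata propagates from either input.  Output values lie in [-1, 1]
    for non-negative inputs.
    """
    if not a.grid.matches(b.grid):
        raise GridAlignmentError("rasters are not on the same grid")
    num = a.values - b.values
    den = a.values + b.values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return Raster(grid=a.grid, values=out, nodata_mask=a.nodata_mask | b.nodata_mask)


def bootstrap_interval(
    stack: np.ndarray,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    statistic=np.mean,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap interval across the realisation axis.

    ``stack`` has shape ``(n_realizations, ...)`` — per-seed rasters or
    per-unit tables.  Realisations are resampled with replacement
    ``n_boot`` times, the statistic (default mean) computed along axis 0
    per resample, and the [alpha/2, 1 - alpha/2] percentiles returned as
    ``(lower, upper, ess)``.  ``ess`` is the effective sample size per
    element (realisations that are finite), reported because elements
    backed by few realisations deserve caution.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 1 or stack.shape[0] < 2:
        raise ValueError("need at least 2 realizations to bootstrap")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = stack.shape[0]
    boots = np.empty((n_boot,) + stack.shape[1:], dtype=float)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = statistic(stack[idx], axis=0)
    lower = np.percentile(boots, 100 * alpha / 2.0, axis=0)
    upper = np.percentile(boots, 100 * (1.0 - alpha / 2.0), axis=0)
    ess = np.isfinite(stack).sum(axis=0)
    return lower, upper, ess
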