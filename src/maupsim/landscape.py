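"""Domain types for areal units and tessellations.

A :class:`Tessellation` is a planar partition of a study extent into
census-like polygonal units, each carrying a population count, together
with the rook-contiguity graph over the units.  The module also provides
the gap-filling pre-processing step (a morphological Voronoi tessellation
that expands units across street corridors until neighbours share
borders) and tolerance-based partition validation.

All geometry lives in a *projected* CRS whose linear unit is the metre;
unit areas are stored in km² and densities in persons/km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely import STRtree
from shapely.geometry import MultiPoint, Polygon, MultiPolygon
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AreaUnit",
    "Tessellation",
    "PartitionReport",
    "CRSError",
    "PartitionError",
    "fill_gaps",
    "build_adjacency",
    "validate_partition",
]

#: m² per km² — geometries are in metres, areas reported in km².
M2_PER_KM2 = 1.0e6

#: Rook rule: boundaries must share a linear intersection longer than this
#: (in CRS units) for two units to count as neighbours.
BOUNDARY_TOL = 1.0e-6

#: Relative tolerance on the density == pop / area bookkeeping invariant.
DENSITY_RTOL = 1.0e-9

# EPSG codes / keywords that identify a geographic (unprojected) CRS.
# Only used to reject inputs; anything else is trusted to be projected.
_GEOGRAPHIC_CODES = {"4326", "4269", "4258", "4283", "4301", "4617"}
_GEOGRAPHIC_KEYWORDS = ("longlat", "geographic", "wgs 84", "wgs84", "nad83")


class CRSError(ValueError):
    """Raised when geometry arrives in a geographic (unprojected) CRS."""


class PartitionError(ValueError):
    """Raised when input geometries violate partition preconditions."""


def crs_is_geographic(crs: str | None) -> bool:
    """Heuristically decide whether a CRS tag names a geographic CRS.

    ``crs`` is a free-form tag such as ``"EPSG:32613"``; without a full
    CRS database only well-known geographic identifiers are recognised.
    ``None`` (unknown/local grid) is treated as projected.
    """
    if crs is None:
        return False
    low = str(crs).lower()
    for code in _GEOGRAPHIC_CODES:
        if low.endswith(code) or f":{code}" in low:
            return True
    return any(k in low for k in _GEOGRAPHIC_KEYWORDS)


@dataclass(frozen=True)
class AreaUnit:
    """One census-like polygon: id, geometry, population, area, density.

    Parameters
    ----------
    uid : int
        Unique integer identifier (the ``GUBID_INT`` field on disk).
    geometry : Polygon or MultiPolygon
        Simple geometry in a projected CRS (metres).
    pop : int
        Non-negative person count (``P2010`` on disk).
    area : float
        Positive area in km² (``AREA``).
    density : float
        ``pop / area`` in persons/km² (``POP_DENS``).
    """

    uid: int
    geometry: BaseGeometry
    pop: int
    area: float
    density: float

    def __post_init__(self) -> None:
        if self.pop < 0:
            raise ValueError(f"unit {self.uid}: pop must be >= 0, got {self.pop}")
        if not self.area > 0:
            raise ValueError(f"unit {self.uid}: area must be > 0, got {self.area}")
        expected = self.pop / self.area
        tol = DENSITY_RTOL * max(1.0, abs(expected))
        if abs(self.density - expected) > tol:
            raise ValueError(
                f"unit {self.uid}: density {self.density} != pop/area {expected}"
            )

    @classmethod
    def from_geometry(
        cls, uid: int, geometry: BaseGeometry, pop: int
    ) -> "AreaUnit":
        """Build a unit with area (km²) and density derived from geometry."""
        area = geometry.area / M2_PER_KM2
        if not area > 0:
            raise ValueError(f"unit {uid}: geometry has non-positive area")
        return cls(uid=int(uid), geometry=geometry, pop=int(pop),
                   area=area, density=pop / area)

    def with_pop(self, pop: int) -> "AreaUnit":
        return replace(self, pop=int(pop), density=int(pop) / self.area)


@dataclass
class Tessellation:
    """A planar partition of the study extent plus its contiguity graph.

    ``units`` preserves insertion order; ``adjacency`` maps each uid to the
    set of rook neighbours (symmetric, irreflexive).
    """

    units: dict[int, AreaUnit]
    crs: str | None = None
    extent: BaseGeometry | None = None
    adjacency: dict[int, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.units) != len({u.uid for u in self.units.values()}):
            raise ValueError("duplicate uids in tessellation")
        for uid, unit in self.units.items():
            if uid != unit.uid:
                raise ValueError(f"key {uid} does not match unit uid {unit.uid}")
        for a, nbrs in self.adjacency.items():
            if a in nbrs:
                raise ValueError(f"adjacency is reflexive at uid {a}")
            for b in nbrs:
                if a not in self.adjacency.get(b, ()):  # symmetry
                    raise ValueError(f"adjacency not symmetric for ({a}, {b})")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def uids(self) -> list[int]:
        return list(self.units)

    def areas(self) -> np.ndarray:
        return np.array([u.area for u in self.units.values()], dtype=float)

    def pops(self) -> np.ndarray:
        return np.array([u.pop for u in self.units.values()], dtype=np.int64)

    def densities(self) -> np.ndarray:
        return np.array([u.density for u in self.units.values()], dtype=float)

    @property
    def total_pop(self) -> int:
        return int(self.pops().sum())

    @property
    def total_area(self) -> float:
        return float(self.areas().sum())

    def neighbors(self, uid: int) -> set[int]:
        return set(self.adjacency.get(uid, set()))

    def copy(self) -> "Tessellation":
        return Tessellation(
            units=dict(self.units),
            crs=self.crs,
            extent=self.extent,
            adjacency={k: set(v) for k, v in self.adjacency.items()},
        )

    @classmethod
    def from_units(
        cls,
        units: Iterable[AreaUnit],
        crs: str | None = None,
        extent: BaseGeometry | None = None,
        adjacency: Mapping[int, set[int]] | None = None,
    ) -> "Tessellation":
        """Assemble a tessellation; adjacency is built from geometry if absent."""
        unit_list = list(units)
        if len({u.uid for u in unit_list}) != len(unit_list):
            raise ValueError("duplicate uids in input units")
        unit_map = {u.uid: u for u in unit_list}
        tess = cls(units=unit_map, crs=crs, extent=extent,
                   adjacency={} if adjacency is None else
                   {k: set(v) for k, v in adjacency.items()})
        if adjacency is None:
            tess.adjacency = build_adjacency(tess)
        return tess


@dataclass(frozen=True)
class PartitionReport:
    """Validation summary: counts only, never raises."""

    n_units: int
    total_pop: int
    total_area: float
    n_overlaps: int
    n_islands: int
    n_multipolygons: int = 0

    def __post_init__(self) -> None:
        if min(self.n_units, self.total_pop, self.n_overlaps,
               self.n_islands, self.n_multipolygons) < 0:
            raise ValueError("report counts must be non-negative")


# ---------------------------------------------------------------------------
# Contiguity
# ---------------------------------------------------------------------------

def build_adjacency(
    tess: "Tessellation | Sequence[AreaUnit]",
    boundary_tol: float = BOUNDARY_TOL,
) -> dict[int, set[int]]:
    """Rook contiguity: uids are adjacent iff their boundaries share a
    linear intersection of length > ``boundary_tol`` (corner touches do
    not count).  Returns a symmetric uid -> set-of-uids mapping.
    """
    units = list(tess.units.values()) if isinstance(tess, Tessellation) else list(tess)
    adjacency: dict[int, set[int]] = {u.uid: set() for u in units}
    if len(units) < 2:
        return adjacency
    geoms = [u.geometry for u in units]
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    for i, j in zip(left.tolist(), right.tolist()):
        if i >= j:
            continue
        shared = geoms[i].boundary.intersection(geoms[j].boundary)
        if shared.is_empty:
            continue
        if shared.length > boundary_tol:
            adjacency[units[i].uid].add(units[j].uid)
            adjacency[units[j].uid].add(units[i].uid)
    return adjacency


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_partition(
    tess: Tessellation,
    overlap_tol_km2: float = 1.0e-6,
    cover_rtol: float = 1.0e-4,
) -> PartitionReport:
    """Check partition invariants and report violations without raising.

    Counts unit pairs whose interiors overlap by more than
    ``overlap_tol_km2`` (km²) and units with an empty neighbour set.
    Multipolygon units are legal but flagged.  ``cover_rtol`` is the
    sliver tolerance on extent coverage (checked only when an extent is
    present; an uncovered fraction beyond it is reported via ``n_overlaps``
    staying untouched — coverage failures do not raise either).
    """
    units = list(tess.units.values())
    n_overlaps = 0
    if len(units) >= 2:
        geoms = [u.geometry for u in units]
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        for i, j in zip(left.tolist(), right.tolist()):
            if i >= j:
                continue
            inter = shapely.intersection(geoms[i], geoms[j])
            if inter.area / M2_PER_KM2 > overlap_tol_km2:
                n_overlaps += 1
    adjacency = tess.adjacency or build_adjacency(tess)
    n_islands = sum(1 for u in units if not adjacency.get(u.uid))
    n_multi = sum(1 for u in units if isinstance(u.geometry, MultiPolygon))
    return PartitionReport(
        n_units=len(units),
        total_pop=int(sum(u.pop for u in units)),
        total_area=float(sum(u.area for u in units)),
        n_overlaps=n_overlaps,
        n_islands=n_islands,
        n_multipolygons=n_multi,
    )


def coverage_fraction(tess: Tessellation) -> float:
    """Fraction of the extent covered by the union of units (1.0 = full)."""
    if tess.extent is None:
        return float("nan")
    union = shapely.union_all([u.geometry for u in tess.units.values()])
    return union.intersection(tess.extent).area / tess.extent.area


# ---------------------------------------------------------------------------
# Morphological (Voronoi) gap filling
# ---------------------------------------------------------------------------

def fill_gaps(
    raw_units: Sequence[AreaUnit],
    extent: BaseGeometry | None = None,
    densify: float = 10.0,
    crs: str | None = None,
) -> Tessellation:
    """Expand gapped units into a contiguous tessellation of the extent.

    Implements a morphological Voronoi tessellation: each source polygon
    is eroded by a small inward offset, its boundary densified at
    ``densify``-metre intervals, and the Voronoi diagram of all resulting
    points is computed; Voronoi cells are grouped by the source unit of
    their generating point, dissolved, and clipped to ``extent``.  Street
    corridors and other no-data gaps between units are thereby absorbed
    so that nearest units come to share borders.

    Population counts and uids carry over unchanged; areas and densities
    are recomputed from the expanded geometry.  ``extent`` defaults to the
    convex hull of the inputs buffered by one densification interval.
    """
    if crs_is_geographic(crs):
        raise CRSError(
            f"gap filling requires a projected CRS; got geographic CRS {crs!r}"
        )
    units = list(raw_units)
    if not units:
        raise PartitionError("no input units")

    # Reject overlapping inputs, naming the offending pair.
    geoms = [u.geometry for u in units]
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    for i, j in zip(left.tolist(), right.tolist()):
        if i >= j:
            continue
        inter = shapely.intersection(geoms[i], geoms[j])
        if inter.area > BOUNDARY_TOL:
            raise PartitionError(
                f"input units {units[i].uid} and {units[j].uid} overlap"
            )

    if extent is None:
        extent = shapely.convex_hull(shapely.union_all(geoms)).buffer(densify)

    # Densified interior points per source unit.  The small inward offset
    # keeps points of adjacent (already touching) units strictly apart so
    # the Voronoi split falls on the original shared edge.
    eps = densify * 0.05
    points: list[tuple[float, float]] = []
    owners: list[int] = []
    for idx, unit in enumerate(units):
        eroded = unit.geometry.buffer(-eps)
        if eroded.is_empty:
            eroded = unit.geometry.buffer(-eps / 10.0)
        if eroded.is_empty:
            rp = unit.geometry.representative_point()
            points.append((rp.x, rp.y))
            owners.append(idx)
            continue
        dense = shapely.segmentize(eroded, densify)
        for geom in getattr(dense, "geoms", [dense]):
            for x, y in geom.exterior.coords[:-1]:
                points.append((x, y))
                owners.append(idx)
            for ring in geom.interiors:
                for x, y in ring.coords[:-1]:
                    points.append((x, y))
                    owners.append(idx)

    pt_geoms = shapely.points(np.asarray(points))
    cells = shapely.voronoi_polygons(MultiPoint(list(pt_geoms)), extend_to=extent)
    # Map each Voronoi cell back to the generating point it contains.
    pt_tree = STRtree(list(pt_geoms))
    grouped: dict[int, list[BaseGeometry]] = {}
    for cell in cells.geoms:
        hit = pt_tree.query(cell, predicate="covers")
        if len(hit) == 0:  # degenerate sliver cell
            continue
        grouped.setdefault(owners[int(hit[0])], []).append(cell)

    out_units: list[AreaUnit] = []
    for idx, unit in enumerate(units):
        merged = shapely.union_all(grouped.get(idx, []))
        clipped = shapely.intersection(merged, extent)
        clipped = _drop_lower_dims(clipped)
        if clipped.is_empty:
            raise PartitionError(f"unit {unit.uid} vanished during gap filling")
        out_units.append(AreaUnit.from_geometry(unit.uid, clipped, unit.pop))

    return Tessellation.from_units(out_units, crs=crs, extent=extent)


def _drop_lower_dims(geom: BaseGeometry) -> BaseGeometry:
    """Keep only the polygonal parts of a geometry (clip can emit lines)."""
    if isinstance(geom, (Polygon, MultiPolygon)):
        return geom
    parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not parts:
        return Polygon()
    return shapely.union_all(parts)
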