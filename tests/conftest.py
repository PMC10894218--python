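import numpy as np
import pytest
from shapely.geometry import box

from maupsim import (
    AreaUnit,
    LandscapeSpec,
    Tessellation,
    generate_landscape,
)


def make_grid_tess(nx: int, ny: int, side: float = 1000.0, pops=None) -> Tessellation:
    """Regular nx x ny grid of square units (side in metres, so 1 km²
    per cell at the default); uids start at 1, row-major."""
    units = []
    uid = 0
    for j in range(ny):
        for i in range(nx):
            uid += 1
            pop = pops[uid - 1] if pops is not None else 1
            units.append(
                AreaUnit.from_geometry(
                    uid, box(i * side, j * side, (i + 1) * side, (j + 1) * side), pop
                )
            )
    return Tessellation.from_units(units, extent=box(0, 0, nx * side, ny * side))


def brute_force_adjacency(tess: Tessellation, tol: float = 1e-6) -> dict[int, set[int]]:
    """O(n²) pairwise boundary-intersection oracle for rook contiguity."""
    uids = tess.uids
    adj = {u: set() for u in uids}
    for a in uids:
        for b in uids:
            if a >= b:
                continue
            shared = tess.units[a].geometry.boundary.intersection(
                tess.units[b].geometry.boundary
            )
            if not shared.is_empty and shared.length > tol:
                adj[a].add(b)
                adj[b].add(a)
    return adj


@pytest.fixture(scope="session")
def default_landscape() -> Tessellation:
    return generate_landscape(LandscapeSpec())


@pytest.fixture(scope="session")
def small_landscape() -> Tessellation:
    return generate_landscape(LandscapeSpec(n_units=300, total_pop=60_000, seed=7))
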