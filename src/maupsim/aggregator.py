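"""Quasi-random, density-preserving spatial aggregation simulator.

The simulator coarsens a population tessellation one dissolve at a time:
a unit is selected quasi-randomly — with preference for small-area units,
via selection probabilities that decay along an exponential-type curve
over the min-max-normalised unit areas — and dissolved into the
contiguous neighbour whose population density is most similar.  The two
population counts are summed, areas and densities recomputed, and the
procedure repeats until a target unit count is reached.  Successive
targets in a schedule chain (each level continues from the previous
level's output with the same RNG stream), and each dissolve is recorded
as a :class:`MergeEvent` so any run can be replayed exactly from its log.

Selection weight for unit *i* with normalised area
``z_i = (area_i - min(area)) / (max(area) - min(area))``::

    w_i = 1 / (1 + z_i**rho),      P(selection)_i = w_i / sum_j w_j

``rho`` (default 4) controls how sharply small units are preferred; when
all areas are equal the distribution is uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

from .landscape import AreaUnit, Tessellation

__all__ = [
    "AggregationConfig",
    "SelectionWeights",
    "MergeEvent",
    "MergeLog",
    "SimulationArchive",
    "IslandError",
    "ContiguityError",
    "selection_weights",
    "sample_unit",
    "choose_merge_partner",
    "merge_units",
    "run_to_target",
    "run_schedule",
    "run_simulations",
    "default_schedule",
    "replay",
]

PROB_SUM_TOL = 1.0e-12


class IslandError(RuntimeError):
    """A unit with no neighbours blocked the requested aggregation."""


class ContiguityError(ValueError):
    """A merge was requested between non-adjacent units."""


@dataclass(frozen=True)
class AggregationConfig:
    """Simulation configuration.

    ``rho`` is the scale factor of the selection-probability curve;
    ``schedule`` the strictly decreasing list of target unit counts;
    ``merge_criterion`` one of ``"min-density-diff"`` (default: dissolve
    into the neighbour with the most similar density), ``"variance-loss"``
    (neighbour minimising the loss in density variance across units) or
    ``"random-neighbor"`` (uniform; ablation).
    """

    rho: float = 4.0
    seeds: Sequence[int] = (0,)
    schedule: Sequence[int] = ()
    tie_break: str = "lowest-uid"
    island_policy: str = "exclude-from-selection"
    merge_criterion: str = "min-density-diff"

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        sched = list(self.schedule)
        if any(t < 1 for t in sched):
            raise ValueError("all schedule targets must be >= 1")
        if any(a <= b for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must be strictly decreasing")
        if self.tie_break != "lowest-uid":
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.island_policy != "exclude-from-selection":
            raise ValueError(f"unknown island_policy {self.island_policy!r}")
        if self.merge_criterion not in (
            "min-density-diff", "variance-loss", "random-neighbor"
        ):
            raise ValueError(f"unknown merge_criterion {self.merge_criterion!r}")


@dataclass(frozen=True)
class SelectionWeights:
    """Per-unit selection probabilities (aligned arrays)."""

    uids: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(float(self.probs.sum()) - 1.0) > PROB_SUM_TOL:
            raise ValueError("probabilities must sum to 1")


@dataclass(frozen=True)
class MergeEvent:
    """One dissolve: ``merged_uid`` was absorbed into ``into_uid``."""

    seed: int
    iteration: int
    target: int
    merged_uid: int
    into_uid: int

    def __post_init__(self) -> None:
        if self.merged_uid == self.into_uid:
            raise ValueError("a unit cannot merge with itself")


@dataclass
class MergeLog:
    """Ordered, replayable record of dissolves for one seed trajectory."""

    events: list[MergeEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def targets(self) -> list[int]:
        seen: list[int] = []
        for e in self.events:
            if not seen or seen[-1] != e.target:
                seen.append(e.target)
        return seen

    def upto(self, level: int) -> "MergeLog":
        """Events of the chain down to and including ``level`` (targets
        are descending, so this is every event with target >= level)."""
        return MergeLog([e for e in self.events if e.target >= level])

    def extend(self, other: "MergeLog") -> None:
        self.events.extend(other.events)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def selection_weights(
    tess: Tessellation | Sequence[float], rho: float = 4.0
) -> SelectionWeights:
    """Small-area-preferring selection probabilities over current units.

    Accepts a :class:`Tessellation` or a bare area vector (km²).  With a
    degenerate area range (all equal) the distribution is uniform.
    """
    if isinstance(tess, Tessellation):
        uids = np.array(tess.uids, dtype=np.int64)
        areas = tess.areas()
    else:
        areas = np.asarray(tess, dtype=float)
        uids = np.arange(len(areas), dtype=np.int64)
    if len(areas) < 2:
        raise ValueError("need at least 2 units to form selection weights")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    probs = _weights_from_areas(areas, rho)
    return SelectionWeights(uids=uids, probs=probs)


def _weights_from_areas(areas: np.ndarray, rho: float) -> np.ndarray:
    amin, amax = areas.min(), areas.max()
    if amax == amin:
        return np.full(len(areas), 1.0 / len(areas))
    z = (areas - amin) / (amax - amin)
    w = 1.0 / (1.0 + z**rho)
    return w / w.sum()


def sample_unit(
    weights: SelectionWeights,
    rng: np.random.Generator,
    selectable: np.ndarray | None = None,
) -> int:
    """Draw one uid from the selection distribution.

    ``selectable`` is an optional boolean mask (aligned with
    ``weights.uids``); masked-out units get probability zero and the rest
    are renormalised — this is how the island policy excludes units with
    no neighbours.  Advances ``rng`` deterministically.
    """
    probs = weights.probs
    if selectable is not None:
        probs = np.where(selectable, probs, 0.0)
        total = probs.sum()
        if total <= 0:
            raise IslandError("no selectable unit remains")
        probs = probs / total
    idx = int(rng.choice(len(probs), p=probs))
    return int(weights.uids[idx])


def choose_merge_partner(
    tess: Tessellation,
    uid: int,
    criterion: str = "min-density-diff",
    rng: np.random.Generator | None = None,
) -> int:
    """Neighbour to dissolve ``uid`` into, per the merge criterion.

    Default: the neighbour with the most similar population density
    (minimum |density difference|), ties broken by lowest uid.
    """
    nbrs = sorted(tess.adjacency.get(uid, set()))
    if not nbrs:
        raise IslandError(f"unit {uid} has no neighbours")
    if criterion == "random-neighbor":
        if rng is None:
            raise ValueError("random-neighbor criterion needs an rng")
        return int(nbrs[int(rng.integers(len(nbrs)))])
    d0 = tess.units[uid].density
    if criterion == "min-density-diff":
        return min(nbrs, key=lambda n: (abs(tess.units[n].density - d0), n))
    if criterion == "variance-loss":
        return _variance_loss_partner(tess, uid, nbrs)
    raise ValueError(f"unknown merge criterion {criterion!r}")


def _variance_loss_partner(tess: Tessellation, uid: int, nbrs: list[int]) -> int:
    """Neighbour whose merge least reduces the density variance across units."""
    dens = tess.densities()
    base_var = float(np.var(dens))
    u = tess.units[uid]
    uid_list = tess.uids
    best: tuple[float, int] | None = None
    for n in nbrs:
        v = tess.units[n]
        merged_density = (u.pop + v.pop) / (u.area + v.area)
        d2 = [
            merged_density if w in (uid, n) else dens[k]
            for k, w in enumerate(uid_list)
            if w != uid
        ]
        loss = base_var - float(np.var(d2))
        key = (abs(loss), n)
        if best is None or key < best:
            best = key
    return best[1]


# ---------------------------------------------------------------------------
# Dissolving
# ---------------------------------------------------------------------------

def merge_units(tess: Tessellation, merged_uid: int, into_uid: int) -> Tessellation:
    """Dissolve ``merged_uid`` into adjacent ``into_uid``; returns a new
    tessellation with n-1 units.  The combined unit keeps ``into_uid``,
    its geometry is the union, its population the sum; adjacency of the
    combined unit is the union of both neighbourhoods minus the pair."""
    if into_uid not in tess.adjacency.get(merged_uid, set()):
        raise ContiguityError(
            f"units {merged_uid} and {into_uid} are not adjacent"
        )
    out = tess.copy()
    _merge_in_place(out, merged_uid, into_uid)
    return out


def _merge_in_place(tess: Tessellation, merged_uid: int, into_uid: int) -> None:
    a = tess.units.pop(merged_uid)
    b = tess.units[into_uid]
    geom = shapely.union(a.geometry, b.geometry)
    tess.units[into_uid] = AreaUnit.from_geometry(into_uid, geom, a.pop + b.pop)
    new_nbrs = (tess.adjacency[merged_uid] | tess.adjacency[into_uid]) - {
        merged_uid, into_uid,
    }
    for n in tess.adjacency.pop(merged_uid):
        tess.adjacency[n].discard(merged_uid)
    for n in new_nbrs:
        tess.adjacency[n].add(into_uid)
    tess.adjacency[into_uid] = new_nbrs


# ---------------------------------------------------------------------------
# Iterative runs
# ---------------------------------------------------------------------------

def run_to_target(
    tess: Tessellation,
    target: int,
    cfg: AggregationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[Tessellation, MergeLog]:
    """Dissolve until exactly ``target`` units remain.

    Selection weights are recomputed from current areas at every
    iteration.  Returns the coarsened tessellation and the log of the
    ``n_start - target`` merge events (iteration counter starting at 1).
    Total population is conserved exactly.
    """
    cfg = cfg or AggregationConfig()
    if target > tess.n_units:
        raise ValueError(
            f"target {target} exceeds current unit count {tess.n_units}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_label = _seed_label(seed)
    work = tess.copy()
    log = MergeLog()
    _run_level(work, target, cfg, rng, seed_label, log)
    return work, log


def _seed_label(seed) -> int:
    return int(seed) if not isinstance(seed, np.random.Generator) else -1


def _run_level(
    work: Tessellation,
    target: int,
    cfg: AggregationConfig,
    rng: np.random.Generator,
    seed_label: int,
    log: MergeLog,
) -> None:
    """Dissolve ``work`` in place down to ``target`` units."""
    iteration = 0
    while work.n_units > target:
        iteration += 1
        uids = np.array(work.uids, dtype=np.int64)
        areas = work.areas()
        probs = _weights_from_areas(areas, cfg.rho)
        weights = SelectionWeights(uids=uids, probs=probs)
        selectable = np.array(
            [bool(work.adjacency.get(u, set())) for u in work.uids]
        )
        if not selectable.any():
            raise IslandError(
                f"no unit with neighbours remains at n={work.n_units} "
                f"(remaining uids: {sorted(work.uids)[:20]}...)"
            )
        uid = sample_unit(weights, rng, selectable)
        partner = choose_merge_partner(work, uid, cfg.merge_criterion, rng)
        log.events.append(
            MergeEvent(seed=seed_label, iteration=iteration, target=target,
                       merged_uid=uid, into_uid=partner)
        )
        _merge_in_place(work, uid, partner)


def run_schedule(
    tess: Tessellation,
    cfg: AggregationConfig,
    seed: int,
) -> dict[int, tuple[Tessellation, MergeLog]]:
    """Run the full descending schedule for one seed, chained.

    Each level starts from the previous level's output (never from the
    base), with one continuous RNG stream across the chain, so the 90%
    level derives from the 95% level and so on.  Returns
    ``{target: (tessellation, level_log)}`` in schedule order.
    """
    sched = list(cfg.schedule)
    if not sched:
        raise ValueError("config has an empty schedule")
    if sched[0] > tess.n_units:
        raise ValueError(
            f"first target {sched[0]} exceeds base unit count {tess.n_units}"
        )
    rng = np.random.default_rng(seed)
    work = tess.copy()
    out: dict[int, tuple[Tessellation, MergeLog]] = {}
    for target in sched:
        level_log = MergeLog()
        _run_level(work, target, cfg, rng, int(seed), level_log)
        out[target] = (work.copy(), level_log)
    return out


def concat_logs(levels: dict[int, tuple[Tessellation, MergeLog]]) -> MergeLog:
    """Concatenate per-level logs of one seed chain into one MergeLog."""
    log = MergeLog()
    for _, level_log in levels.values():
        log.extend(level_log)
    return log


@dataclass
class SimulationArchive:
    """Outputs of a multi-seed simulation campaign.

    ``results[(seed, target)]`` holds each level's tessellation and log;
    ``seed_logs[seed]`` the concatenated chain log; ``failures`` maps
    seeds that errored to the exception message (other seeds complete).
    """

    base: Tessellation
    config: AggregationConfig
    results: dict[tuple[int, int], tuple[Tessellation, MergeLog]] = field(
        default_factory=dict
    )
    seed_logs: dict[int, MergeLog] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def seeds(self) -> list[int]:
        return sorted(self.seed_logs)

    @property
    def levels(self) -> list[int]:
        return sorted({t for (_, t) in self.results}, reverse=True)

    def level_tessellations(self, target: int) -> dict[int, Tessellation]:
        return {
            s: tess for (s, t), (tess, _) in self.results.items() if t == target
        }


def run_simulations(
    tess: Tessellation, cfg: AggregationConfig
) -> SimulationArchive:
    """Run the schedule independently for every configured seed.

    Seeds are independent (each gets its own RNG stream), so permuting
    the seed order cannot change any seed's outputs; one seed's failure
    is recorded and does not abort the others.
    """
    archive = SimulationArchive(base=tess, config=cfg)
    for seed in cfg.seeds:
        try:
            levels = run_schedule(tess, cfg, seed)
        except Exception as exc:  # recorded per-seed, campaign continues
            archive.failures[int(seed)] = str(exc)
            continue
        for target, pair in levels.items():
            archive.results[(int(seed), target)] = pair
        archive.seed_logs[int(seed)] = concat_logs(levels)
    return archive


# ---------------------------------------------------------------------------
# Schedules and replay
# ---------------------------------------------------------------------------

def default_schedule(
    n: int, step_fraction: float = 0.05, lowest_fraction: float = 0.10
) -> list[int]:
    """Targets at 95%, 90%, ... down to ``lowest_fraction`` of ``n``.

    Each target is round-half-up of p*n; the list must come out strictly
    decreasing (it cannot for very small ``n``).
    """
    if not 0 < lowest_fraction < 1 - step_fraction:
        raise ValueError("need 0 < lowest_fraction < 1 - step_fraction")
    n_steps = int(round((1.0 - step_fraction - lowest_fraction) / step_fraction)) + 1
    fractions = [1.0 - step_fraction * (i + 1) for i in range(n_steps)]
    targets = [int(math.floor(p * n + 0.5)) for p in fractions]
    if any(a <= b for a, b in zip(targets, targets[1:])) or targets[0] >= n:
        raise ValueError(f"n={n} too small for a strictly decreasing schedule")
    return targets


def replay(base: Tessellation, log: MergeLog) -> Tessellation:
    """Re-apply a merge log to the base tessellation, ignoring weights
    and RNG entirely.  The result must equal the simulator's output for
    the log's final level — this is the replay contract of the log."""
    work = base.copy()
    for e in log.events:
        _merge_in_place(work, e.merged_uid, e.into_uid)
    return work


def replay_partition(base_uids: Sequence[int], log: MergeLog) -> dict[int, int]:
    """Union-find replay: map every base uid to the uid of the coarse unit
    that absorbed it (itself if never merged).  Geometry-free oracle."""
    parent = {u: u for u in base_uids}

    def find(u: int) -> int:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for e in log.events:
        parent[find(e.merged_uid)] = find(e.into_uid)
    return {u: find(u) for u in base_uids}
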