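# Methods

## The aggregation procedure

`maupsim` simulates alternative zonal configurations of a polygonal
population tessellation by iterative, seeded dissolving. One iteration:

1. compute selection probabilities over the *current* units from their
   min–max-normalised areas `z_i`, `w_i = 1 / (1 + z_i^ρ)`, normalised to
   sum to one (uniform when all areas are equal);
2. draw one unit from that distribution;
3. dissolve it into the rook-contiguous neighbour with the most similar
   population density (minimum |Δ density|, ties to the lowest uid);
4. sum the two population counts, union the geometries, recompute area,
   density and the contiguity graph.

Iterations continue until the level's target unit count is reached; a
descending schedule of targets is run chained — each level continues from
the previous level's output with the same RNG stream — so coarse levels are
nested refinements of a single simulation trajectory per seed. Seeds are
fully independent: each gets its own `numpy.random.default_rng(seed)`
stream, so the outputs for a seed do not depend on which other seeds run.

Assumptions: the input is a valid planar partition in a projected CRS
(metres); populations are non-negative integers; every unit has at least
one rook neighbour (units without neighbours get selection probability
zero; if targets become unreachable the run errors rather than merging
non-contiguous units).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `rho` | 4 | shape of the small-area preference curve; larger ρ flattens the penalty for mid-sized units while still down-weighting the largest (ρ→∞ approaches uniform except for the largest units; ρ→0 approaches uniform overall) |
| `schedule` | 95%…10% in 5% steps | target unit counts, round-half-up of p·n |
| `tie_break` | lowest-uid | deterministic partner choice under density ties |
| `island_policy` | exclude-from-selection | neighbourless units are never selected |
| `merge_criterion` | min-density-diff | alternatives: `variance-loss` (minimise the reduction in density variance across units), `random-neighbor` (ablation) |

The pairwise |Δ density| criterion is the operational reading of "merge
with the most similar average population density"; the variance-loss
reading is provided as a pluggable alternative but is O(n) per candidate
and not the default. The `random-neighbor` criterion exists to quantify,
by ablation, how much of the density preservation is due to the
similarity criterion rather than to aggregation arithmetic.

### Selection-weight form

The weight curve is evaluated on min–max-normalised areas with the
exponent applied to the normalised area, `w_i = 1/(1 + z_i^ρ)`. This
reading makes ρ a dimensionless shape parameter and reproduces the
intended behaviour (strong preference for small units, smoothly decaying
with area). An independent brute-force evaluation of this form backs the
test suite.

### Schedule rounding

Targets are round-half-up of p·n. For a 55,146-unit base this gives 18
levels from 52,389 down to 5,515 with a first increment of 2,757 units.
No single rounding rule can make all of the commonly quoted endpoint
figures for such a base mutually consistent; round-half-up is used
uniformly and an explicit target list can always be supplied instead.

## Merge logs and replay

Every dissolve is recorded as `(seed, iteration, target, merged_uid,
into_uid)`, with the iteration counter restarting at 1 within each level.
`replay(base, log)` re-applies a log geometrically, ignoring weights and
RNG; `replay_partition` is a union-find variant that reconstructs the
membership partition without geometry. The replay contract — the replayed
tessellation equals the simulator's level output in uids, populations and
areas — is asserted in the tests and is what makes the archives auditable.

## Synthetic landscapes

The generator emulates the structure of block-level census tessellations
around a large city: seed points are drawn from a mixture of `n_cores`
Gaussian urban cores (fraction `urban_fraction`) plus a uniform rural
background; their Voronoi diagram, clipped to a square extent, gives the
units. Population is a smooth core-peaked density surface times unit area
times multiplicative lognormal noise; a `zero_pop_fraction` quota of the
*largest* units is zeroed (mimicking unpopulated open/rural parcels and
making the zero count deterministic per seed); the remainder is rescaled
to `total_pop` exactly by largest-remainder rounding. A single RNG stream
keyed by `spec.seed` drives all draws in a fixed order, so landscapes are
bit-reproducible.

Default calibration (`n_units=1000`, `extent_km=30`, `n_cores=3`,
`core_sd_km=1.2`, `urban_fraction=0.9`, `zero_pop_fraction=0.08`,
`total_pop=500000`, `density_noise_sd=0.5`): chosen so the landscape
reproduces the qualitative shape facts of real mixed-resolution census
bases — the large majority of units are small urban blocks (area Q3/Q1 of
a few; mean/median area ≈ 13 at this n), a heavy right tail of large
sparse rural units, a clear negative area–density rank correlation
(≈ −0.75), and ~8% unpopulated units. The lognormal log-sd of 0.5 models
block-to-block density heterogeneity around the smooth surface (95% range
≈ 7× between structurally identical blocks).

What the generator does *not* emulate: street networks and true no-data
gaps (units are born contiguous), multi-order administrative hierarchies,
spatially correlated noise beyond the smooth surface, and the 3–4 orders
of magnitude of area range seen in real deposits at n ≈ 55k (at n = 1000
the tail is proportionally shorter). Passing tests therefore demonstrate
the pipeline's behaviour on realistically structured inputs, not
equivalence with any particular census product.

## Gap filling (morphological tessellation)

Gapped inputs (street corridors between blocks) are expanded by Voronoi
tessellation of points densified along each polygon's slightly eroded
boundary (densification interval default 10 m, erosion 5% of it); cells
are grouped by source unit, dissolved and clipped to the extent (default:
convex hull of the inputs buffered by one densification interval). The
inward erosion keeps coincident boundary points of already-touching units
apart, making the operation idempotent (up to vertex tolerance) on inputs
that are already partitions. Unit count and populations carry over
unchanged; areas and densities are recomputed.

## Metrics

- **ASR** = √(mean unit area), km — the standard single-length summary of
  zonal coarseness.
- **Distribution summaries** pool units across all seeds of a level and
  report natural-log median, mean and empirical 2.5/97.5 percentiles.
  Zero-population units are excluded from the log-pop and log-density
  summaries, with the exclusion count reported. Percentiles use the
  inverted-CDF (empirical) definition, which is invariant under pooling
  identical seeds.
- **Merge frequency**: for each original unit and level, the number of
  seeds in which it was merged with at least one other unit by that point
  in the chain — the effective sample size caveat for per-unit bootstrap
  statistics.
- **NDPI** = (A − B)/(A + B) per pixel; 0/0 → 0 by convention (both
  surfaces agree nobody lives there), keeping the output bounded in
  [−1, 1].
- **Bootstrap intervals**: percentile method across the realisation axis
  (default 1,000 resamples, statistic = mean), with per-element effective
  sample sizes reported.

## Dasymetric disaggregation

Pixel membership is by centre containment (a centre exactly on a shared
edge goes to the lower uid); each unit's count is split over its pixels
proportionally to a non-negative weight raster (or uniformly). Mass
preservation is exact by construction: per-unit pixel sums equal the unit
count to 1e-9 relative, and the raster total equals the tessellation
total. Degenerate cases: a unit with all-zero weights falls back to
uniform (recorded); a unit capturing no pixel centre places its whole
count on the pixel nearest its centroid (recorded with the receiving
pixel) rather than dropping mass. The weight raster is an interface: any
externally trained model (e.g. a random-forest weighting surface) can
supply it; none is trained here.

## Numerical choices

- Areas stored in km² (geometry in metres; conversion 1e6), densities in
  persons/km²; `density == pop/area` enforced to 1e-9 relative.
- Rook contiguity: shared boundary intersection length > 1e-6 CRS units.
- Partition validation tolerances: pairwise interior overlap ≤ 1e-6 km²;
  multipolygon units allowed but flagged.
- Selection probabilities must sum to 1 within 1e-12.
- RNG: `numpy.random.default_rng` (PCG64) everywhere; every stochastic
  component takes an explicit seed or Generator.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on synthetic landscapes of
500–2,000 units with full 18-level chains (10–20 seeds for the stochastic
properties, two seeds for NDPI comparisons on a 300 m grid). These sizes
exercise every code path at desk scale; the simulator itself is O(n) per
dissolve in the weight recomputation and has been run at 2,000 units
without special handling.

## Known limitations

- Vector I/O is GeoJSON; Shapefile/GeoPackage are recognised but rejected
  with a clear error. Rasters are ESRI ASCII grids (plain text).
- CRS handling is a tag, not a full CRS database: geographic inputs are
  rejected by a known-code denylist, and areas are always computed in the
  planar CRS (no geodesic areas).
- The variance-loss merge criterion is exact but slow for high-degree
  units; the default pairwise criterion is the tested path.
- Merging is strictly pairwise and contiguous; no topology repair is
  attempted on invalid inputs beyond tolerance-based validation.
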