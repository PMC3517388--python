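# Methods

This note records the models implemented in `accessgrid`, the assumptions
behind them, the defaults and why, and the places where the design was
genuinely open and a choice had to be made.

## Grids and geometry

All layers share one grid model: projected coordinates in meters, square
cells (default 90 m), row 0 northernmost, a cell located at its center.
Stages **fail fast on misalignment** instead of resampling silently;
resampling is an explicit step (`resample_to`), nearest-neighbour for
categorical layers (never inventing a class code) and bilinear for
continuous ones. The 90 m default matches the resolution at which the
elevation and population grids are conventionally harmonized for this
kind of analysis.

## Friction surface

Landcover is a 13-class categorical raster; rivers, water-body polygons
and 3-class roads are rasterized onto it with precedence
`landcover < water < rivers < roads`, so a road crossing a river remains
traversable — the crossing cell is read as a bridge. Within the road
layer the precedence is rural < district < national, making the merge
independent of feature order. Lines are rasterized with an *all-touched*
rule (every cell the segment passes through), because at 90 m a
center-sampling rule breaks thin diagonal roads into disconnected
fragments and the least-cost search needs road continuity.

## Speed model

Per scenario, each class maps to a speed (km/h) and a locomotion mode.
Off-road walking speeds range from 1 km/h (flooded shrubland, dense
evergreen forest) to 5 km/h (built-up areas); roads are walked at 5 km/h
in scenario 1, cycled at 10 km/h in scenario 2, and in scenario 3
motorized at 50 km/h (national) and 20 km/h (district) while rural/feeder
roads stay on foot. Water is a barrier (speed 0) everywhere. The shipped
table (`src/accessgrid/data/speeds.yaml`) can be replaced wholesale via
configuration.

Motorized travel can be restricted to a region (a transit mask polygon),
reflecting that minibus service may exist only in particular districts;
outside the mask, national/district road cells fall back to walking at
5 km/h. The default mask is the whole domain.

### Slope corrections

Slopes are computed between adjacent cell centers from the DEM, in the
patient's direction of motion (toward the facility), which makes the cost
surface anisotropic: climbing to a hilltop facility is slower than
descending to a valley one over the same transect.

* **Walking** uses Tobler's hiking function, `6·exp(−3.5·|s + 0.05|)`
  km/h, rescaled so its flat value equals the class base speed (the
  published class speeds are flat-surface speeds; the canonical function's
  flat value is 6·e^−0.175 ≈ 5.04 km/h). Fastest slightly downhill
  (s = −0.05), decaying with slope magnitude, always positive.
* **Cycling** has no canonical published formula; the implemented model is
  a constant-power balance: the power needed to hold the base speed on the
  flat (rolling resistance `Crr = 0.008`, total mass 90 kg, aerodynamic
  constant `0.5·ρ·CdA = 0.3 kg/m`) is held fixed and the speed at slope
  `s` solves `0.3·v³ + (Crr + s)·m·g·v = P₀`. Downhill speed is capped at
  1.5× the flat speed (cautious descent on unpaved roads), and the speed
  is floored by the slope-corrected 5 km/h road *walking* speed: at
  realistic power a 5% climb drops the riding speed below walking pace,
  at which point the rider dismounts and pushes. The floor also preserves
  the dominance property that adding a bicycle never slows a journey.
  All parameters are configurable; the model is deliberately simple and
  flagged for sensitivity analysis.
* **Motorized** speeds ignore slope.

### Travel-time accumulation

Travel time from every cell to its nearest facility is Dijkstra's
algorithm on the 8-connected grid graph (diagonal length √2·cell), with
the half-cell harmonic edge cost `t = (d/2)·(1/v_A + 1/v_B)` — the
standard raster cost-distance convention, which reduces resolution bias
relative to whole-cell costs. Times beyond the cap (default 60 minutes,
the one-hour access norm) are nodata; an auxiliary mask distinguishes
beyond-cap from topologically unreachable (e.g. cut off by water) cells.
The search is validated against a brute-force edge-relaxation oracle on
random grids.

## Dasymetric population surface

A sector is *pure* when all of its non-excluded cells carry one inhabited
landcover class; its density (population / area of those cells) is an
empirical sample of that class's density. Class weights are the mean
density over pure sectors, rescaled to max 1. Judging purity on
non-excluded cells (rather than literally all cells) is a deliberate
reading: once roads are burned into the merged surface almost no sector
is literally single-class, and for a sector with no mapped exclusions the
two definitions coincide. Classes never observed alone default to the
mean of the estimated weights (configurable; `zero` also available).

Redistribution assigns each cell to the sector containing its center — a
partition, so conservation is exact — and spreads the sector total in
proportion to cell weights, with exclusion classes (water, all road
classes) at exactly zero. A sector with people but only excluded cells is
an error (its population would be unplaceable); the generator instead
assigns such sectors zero population. Roads are excluded for *population*
but remain traversable for *cost*: the two grids are different readings
of the same merged surface.

## Facility cleaning

Rows missing coordinates and/or capacity are excluded and tallied by
missingness pattern (both / coordinates only / capacity only);
percentages are reported to one decimal, rounded half-up. Included
facilities landing on water are relocated to the nearest traversable cell
by Euclidean center distance, ties broken by ascending (row, column).
This automates what is conventionally a manual GIS step; the manual
practice of checking that a facility lands on the correct river bank is
approximated by nearest-cell relocation and noted as an approximation.
Duplicate ids and non-positive capacities are hard errors.

## Catchment allocation

Facilities are processed sequentially in a configurable order (default:
table order). Each facility sorts the still-unclaimed cells with travel
time ≤ cap by (time, row, column) and claims them while the cumulative
claimed population stays **strictly below** capacity — it stops before
the cell that would reach or exceed it, so allocation is whole-cell,
deterministic and conservative. The limiting factor is `max_capacity`
when reachable cells remained, else `max_travel_time`. Travel-time ties
between facilities go to the earlier-processed facility. Because the
sequential policy on contested cells is a modelling choice with no
canonical answer, `order_sensitivity` measures the spread of total
covered population across random orders instead of hiding it.

The coverage report is exactly conservative (covered + underserved =
total) and its percentages are count ratios rounded half-up to one
decimal.

## Synthetic landscapes

The generator emulates the structure of a mountainous, densely farmed
province bordered by a lake: a Gaussian-field DEM scaled to a relief
amplitude; a Voronoi tessellation of sectors (built exactly from cell
squares, so the dasymetric partition assumption holds by construction);
landcover patches over the 12 inhabited classes by nearest-seed growth,
with a configurable quota of sectors forced to a single class (the
default quota of 12 puts one pure sector behind each class, round-robin,
so density estimation is always possible); per-class minimum-spanning-tree
road networks (connected after all-touched rasterization); rivers
crossing the domain; one lake polygon; and facilities placed near
population with log-normal capacities, injected missingness and deliberate
on-water placements. Sector populations are drawn from known per-class
densities with small log-normal noise (σ = 2%) and forced to the
configured total exactly by largest-remainder rounding. One seed drives
everything through per-layer substreams; equal seeds give byte-identical
bundles.

Nominal defaults carry the study-scale bookkeeping: 2,091,065 people,
97 sectors, 113 facilities of which 9 lack both coordinates and capacity,
7 coordinates only, 3 capacity only, and 3 sit on water (so the cleaning
stage reports 94 included, 83.2%).

### Scaling, and what passing tests show

Tests and the acceptance script run a scaled-down landscape: 150×150
cells (13.5 km), relief 700 m, 24 sectors, 9 facilities, 250,000 people,
capacity mean 40,000. These sizes are the package's own choice of test
conditions. They are calibrated so the *regime* matches the setting the
method is meant for: under walking, most facilities are travel-time
limited (capacity rarely binds) and coverage is partial, rising across
scenarios. Relief scales with the domain because shrinking the extent
without shrinking relief produces unrealistically steep terrain.

The scenario-monotonicity property (faster modes cover at least as many
people) is a property of that regime, not of the allocator in general:
when most facilities are capacity-limited, sequential allocation can
strand demand as fast roads let early facilities claim distant dense
cells — a real behaviour of capacity-constrained sequential catchments,
observable by pushing `capacity_mean` down.

What the generator does **not** emulate: realistic hydrology or road
morphology, spatial autocorrelation of missingness, facility siting
politics, and real admin-boundary shapes. Passing tests therefore
demonstrate correctness of the arithmetic, the search, conservation, and
the regime-level behaviour — not predictive accuracy on any real
province.

## Numerical choices

* Percentages: decimal round-half-up at 1 decimal, matching the reporting
  convention of such tables.
* Cycling speeds are interpolated from a 2401-point table over slope
  ∈ [−3, 3] (root-solving per edge would be exact but ~100× slower; the
  interpolation error is far below the model's own uncertainty).
* Float grids round-trip ASCII via `repr`, preserving values bit-for-bit
  in practice; integer grids round-trip exactly.
* Degenerate inputs fail loudly: empty grids, non-square cells, unknown
  class codes or scenarios, orders that are not permutations, negative
  populations, facilities on barriers with no traversable cell anywhere.

## Known limitations

* Single-band rasters only; no reprojection (inputs must share a
  projected CRS in meters), no tiling — domains are assumed to fit in
  memory.
* The cycling slope model is a stand-in with made explicit parameters;
  conclusions sensitive to scenario 2 should vary them.
* Whole-cell allocation means a facility's served population can
  undershoot capacity by up to one cell's population.
* Relocation of water-sitting facilities ignores which river bank the
  facility belongs to.
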