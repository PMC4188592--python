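# Methods

## The problem

Trawl surveys yield one georeferenced catch weight per tow for an
aggregating benthic taxon. The taxon's full distribution includes a broad
scatter of dispersed individuals; the habitat worth protecting is the dense
aggregation. The pipeline turns point catches into a smooth biomass surface
and asks at which surface level the enclosed area stops tracing
aggregations and starts absorbing the dispersed background. That level — a
catch weight, because of the surface scaling chosen below — defines the
"significant concentration" polygons.

## Survey harmonization

Different gears and tow durations sample small individuals differently,
while large catches are governed by whether the tow crossed an aggregation
at all. The harmonization module therefore looks for the smallest catch
weight `t` such that the two-sample Kolmogorov–Smirnov test on the records
`>= t` (and on every higher rung of the weight ladder) is non-significant;
duration groups within the reference gear are compared first, then the
pooled reference gear against each remaining gear from that rung upward,
and the combinable threshold is the larger of the two answers. Records
below it are dropped before density estimation.

Decisions and caveats:

* Per-rung tests are deliberately uncorrected for multiplicity: each rung
  is an autonomous "pool from here up?" decision at raw α (default 0.05),
  and every result's decision note says so. The practical consequence is an
  irreducible ~5% false-alarm rate per independent null rung; the
  harmonization-recovery study below runs at its ceiling (~94%) for that
  reason.
* p-values are exact for `min(n) <= 150` and asymptotic above. The
  asymptotic approximation is measurably anticonservative in the low
  hundreds (empirical size ≈ 0.06 at n ≈ 120 for nominal 0.05) and the
  exact computation is cheap at those sizes.
* Zero catches are treated as absences: ladders run on positive records.
* Rungs where either restricted sample has fewer than `min_n = 5` records
  are reported but excluded from the decision; 5–9 records are tested but
  flagged unreliable.
* If pooling would retain less than 10% of the positive records the result
  recommends separate per-region models instead (small, weakly aggregated
  taxa can lose nearly everything to the cut).

## Density surface

The Silverman quadratic kernel `K(u) = (3/π)(1 − u²)², u ≤ 1` — the
"quadratic (Epanechnikov)" kernel of standard GIS density tools — is summed
over all positive catches at each raster cell center. Two scalings:

* **density** (kg·m⁻²): kernels integrate to their catch weight, so the
  raster conserves total biomass. Used for mass-conservation testing.
* **peak** (default): each kernel's maximum equals its catch weight, so an
  isolated 75 kg catch peaks at exactly 75 and contour levels are catch
  weights. The two scalings differ by the exact scalar `πh²/3` everywhere,
  so polygons and threshold selection are scaling-invariant up to level
  relabelling.

Geometry defaults follow the common GIS rule: search radius `h` = shortest
extent side / 30, cell = side / 250 (a ~600 km survey extent gives
h ≈ 20 km and ~2.4 km cells). The raster is grown outward by `h` and
snapped to whole cells so no kernel is ever clipped — clipping would break
mass conservation. Values are evaluated at cell centers (standard raster
semantics), and every cell farther than `h` from all catches is exactly
zero. The analysis extent defaults to the tight bounding box of the points;
an explicit extent (e.g. a fishing-footprint mask) can be passed instead.

Biomass weighting is the default reading — the surface is a biomass
surface, and thresholds are quoted in kg; an unweighted count surface is
available via unit weights.

## Threshold–area curve

Superlevel sets `{surface >= t}` are contoured by marching squares with
linear interpolation on cell-center values; the raster is padded with one
sub-level ring so all contours close. Rings are nested by containment
parity (even depth = exterior, odd = hole), areas are computed from the
vector polygons in km² (holes subtracted) and cross-checked against the
raster cell count within a boundary-cell tolerance band. Point-in-polygon
tests are boundary-inclusive (thresholds are "at or above"). Per step the
curve records: total area, newly enclosed points, new points outside the
previous polygons' union ("in new areas"), polygons that merge two or more
predecessors, brand-new polygons, and raster-edge contact flags.

The default level grid is log-spaced over the positive catch-weight
distribution, from its 90th percentile (by which level the aggregation
cores are established) down to its 5th (the weight scale of single
dispersed individuals), 16 levels. Log spacing matches catch weights that
span decades; grids mirroring published weight-class tables can be passed
explicitly.

## Threshold selection

The curve's canonical shape has three phases: slow growth while thresholds
map out the aggregations (the establishment plateau), a rapid expansion as
dispersed individuals flood in, and eventual stabilization over the full
distribution. The selected threshold demarcates the onset of the rapid
phase:

1. **Establishment plateau**: the maximal leading run of successive-step
   area ratios within `1 + plateau_tol` (default 0.10) after the first
   non-empty step.
2. **Candidates**: later steps with area ratio ≥ `jump_min` (default 1.2),
   reported ranked by ratio.
3. **Vetoes** (flags, never silent): `single-point-jump` if fewer than
   `min_new_points = 3` new records carry the jump; `merge-without-support`
   if >50% of the jump's growth comes from polygon merges whose bridging
   regions hold fewer than `min_spread = 2` records; `low-density-new-area`
   if the newly added area's mean surface value is below half the candidate
   level. Curves with no candidate are flagged `gradual-increase` (steady
   growth, no single defining jump — no aggregation signal) or
   `no-large-jump`.
4. **Selection**: the *first* (highest-threshold) unflagged candidate wins,
   and the selected value is the jump's upper level. Once the curve has
   entered its rapid phase, deeper steps keep inflating area with
   background individuals and often carry even larger ratios; ranking by
   ratio alone would chase them downward, so a vetoed high candidate passes
   the nomination to the next candidate rather than to the largest ratio.

Every constant lives in `SelectionCriteria`; the defaults are declared
judgment values, not estimates. The result carries a human-readable
narrative plus machine-readable flags. Polygons resting on a single record
are additionally flagged `insufficient_data` in exports: they may be real
concentrations whose extent needs targeted sampling, and are never dropped.

The enclosure summary reports the share of total recorded biomass inside
the selected polygons and the polygons' share of the sampled area; the
sampled area defaults to the convex hull of all trawl locations (null sets
included) and can be overridden with an explicit mask polygon.

## Synthetic scenes and what they do (not) show

`generate_scene` draws a Thomas cluster process: Poisson parents (expected
8 over a 600 × 600 km window), Poisson(40) offspring per parent displaced
by an isotropic Gaussian (sd 8 km, truncated at 4 sd so truth statements
are exact), plus a Poisson background (expected 300 dispersed sets). Catch
weights are lognormal — median 30 kg (log-sd 0.8) for cluster members,
median 0.2 kg (log-sd 0.25) for background — a ~150-fold contrast typical
of habitat-forming sponge catches versus dispersed individuals; 30% of sets
are nulls (zero inflation). Everything derives from one integer seed.

`make_multisurvey` splits a scene into alternating vertical strata (width
one cluster-sd) assigned round-robin to gears, so every aggregation is
sampled by all gears — emulating overlapping depth-stratified designs.
One contiguous block per gear would instead confound gear effects with real
spatial biomass differences and no weight cut could reconcile the surveys.
Gear effects multiply catches below a cutoff only (catchability of small
individuals).

Ground truth for end-to-end scoring: the generator's cluster/background
boundary is the 95th percentile of the background weight distribution
(0.30 kg under defaults) — the catch level separating aggregations from
dispersed individuals. Two independent definitions (the maximum surface
value beyond every cluster's reach, and the level whose superlevel set best
matches the truth regions dilated by `h`, by Jaccard) bracket the same one
to two grid steps on test scenes.

What passing these tests does **not** show about real data: the generator
has stationary clusters, isotropic displacement, no depth stratification or
bathymetric structure, iid marks, and a clean two-regime weight mixture.
Real surveys have spatially varying effort and catchability, habitat edges
that follow topography, and weight distributions without a crisp background
edge; on such data the curve's jump can be broader and the selection
narrative (and its flags) matters more than the point estimate.

## Numerical choices

* Marching squares with linear interpolation on cell centers; contour areas
  in projected m², reported in km².
* Merge detection requires genuine level-set connectivity (interior
  overlap with two or more predecessor polygons); polygons merely within a
  cell diagonal of each other are not merged.
* Nesting and monotonicity assertions use a tolerance of one cell diagonal.
* The recovery studies use scenes of ~450–900 sets on ~270² rasters with
  16-level grids — the full pipeline runs in under a second per scene, and
  the 100-scene studies in about a minute.
* Degenerate inputs fail loudly: empty samples, non-positive contour
  levels, non-monotone level grids, all-coincident points, zero total
  biomass.

## Known limitations

* The selection constants (`jump_min`, `min_new_points`, …) encode expert
  judgment; they are exposed, not fitted. On curves without a clear
  two-phase shape the method correctly declines to select.
* Polygon outer boundaries inherit the kernel halo: they can extend up to
  `h` beyond the outermost supporting catch. Boundary refinement (targeted
  survey, bathymetry, habitat models) is out of scope; the halo can also be
  read as a precautionary buffer.
* The KS ladder inherits the raw-α false-alarm floor discussed above, and
  pooling decisions are confounded by real spatial differences when surveys
  do not overlap spatially.
* Areas are planar: inputs must be in an equal-area-adequate projection for
  the region analysed.
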