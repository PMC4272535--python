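# Methods

This note records the models, conventions and numerical choices behind
`stmc`, and what the synthetic generators do and do not emulate.

## Pseudo-3D traces and STML

A trace is a time-ordered sequence of states.  Each state carries scalar
numeric state variables and, per spatial state variable, an m×n matrix of
non-negative reals (a *pseudo-3D* grid: 2-D space plus a density value per
position — the proportion/count of occupants, never an explicit third
axis).  Analysed traces are stored as STML XML: a non-empty list of
`<timepoint>` elements, each holding `<spatialEntity>/<pseudo3D>` records
(type `region` or `cluster`, eleven measure children, optional `shape`)
and `<numericStateVariable>` records.  The normative structure is
`src/stmc/schema/STML_L1V1.xsd`; the reader accepts any declared `LxVy`
version string but validates against L1V1 only, with a warning.

Missing timepoint values are resolved as: the predefined value if given;
0 for the first timepoint; otherwise the previous resolved value plus one.
Resolution must yield strictly increasing values and is idempotent.
Duplicate numeric-variable names within a timepoint are an error.  Numbers
are serialised positionally (no exponent) at shortest round-trip precision,
so write→read is the identity on valid experiments.

## Region detection

Grids are converted to grayscale by `round(255·min(1, v/normMax))`
(round-half-up; `normMax` defaults to the grid maximum).  The pipeline then
applies, in order: linear brightness/contrast (`α·I + β`, saturated to
[0,255]), greyscale morphological closing (3×3 square element, n dilations
then n erosions, nearest-border), separable Gaussian blur (odd kernel k;
σ ≤ 0 derives σ from k as `0.3·((k−1)/2 − 1) + 0.8`, mirror border),
binary threshold (strictly above → foreground), 8-connected component
labelling, Moore boundary tracing, and Douglas–Peucker polygonal
approximation at the configured tolerance.  Components with
`|pixels| > ε_size` (strict) become regions, reported in (centroidY,
centroidX) order.

Conventions: grids are row-major, 0-based, position (row, col); polygons
use (x=col, y=row) with y growing downward; contours trace pixel centres;
`|positions|` counts pixels, while area/perimeter are polygon quantities
of the pixel-centre contour (an s×s block has pixel count s² but polygon
area (s−1)²).  Holes are 4-connected background components enclosed by a
region, traced the same way.  The value threshold of the region definition
is realised on the intensity scale: callers convert a raw-value threshold
via `round(255·THRESHOLD/normMax)`, matching a pipeline that thresholds
the image rather than the grid.  Because the blur alters values before
thresholding, the post-blur threshold is normative.

The boundary tracer follows the Moore neighbourhood clockwise from the
last background cell inspected.  Since the (pixel, backtrack) state
evolves deterministically, the walk is eventually periodic; the contour is
the orbit of the first repeated state, which closes the boundary exactly
once regardless of spurs or one-pixel-wide appendages (a fixed stopping
heuristic such as "revisit the start pixel" fails on such shapes).

`point_mode` bypasses closing/blur/contours entirely: every position with
intensity at or above the threshold becomes a one-pixel region.  This is
the lightweight cell detector used for traces whose entities occupy single
positions (chemotaxis); pileup is preserved in the position's value.

## Cluster detection

Regions are clustered with DBSCAN over the centroid-distance pseudometric
(Euclidean distance of centroids; distinct entities at the same location
have distance 0, hence *pseudo*-metric).  A region is a core when at least
`min_neighbours` regions (itself included) lie within `ε_distance`
(default 2 — any region with a neighbour).  Clusters are the connected
components of cores under ε-reachability; border regions (non-core,
within ε of a core) are assigned to the cluster of their nearest core,
ties broken by the lowest cluster label after canonical sorting of the
input.  This border rule is what makes the output invariant under input
permutation — classical DBSCAN assigns shared border points to whichever
cluster reaches them first.  Clusters with `|C| ≤ ε_size` (strict) are
discarded.  `min_neighbours` is exposed because with the minimal value 2
border points cannot exist and the order-independence rule would be
vacuous.

## Spatial measures

For a region: clusteredness = area/(area + Σ hole areas) (1 when
hole-free); density = mean grid value over the covered pixels; area =
outer-polygon area minus hole areas (shoelace); perimeter = closed
polyline length of the outer contour (holes ignored); distance from origin
= distance from the filled outer polygon to the grid centre
((n−1)/2, (m−1)/2), 0 if the origin is inside; centroid from polygon
moments.  The angle is constructed by cutting the convex hull with the
line through the centroid perpendicular to the origin–centroid segment and
measuring the angle the two extreme intersection points subtend at the
origin; 360° when the origin lies in the hull, 0° for point-like hulls or
centroid-at-origin.  When the perpendicular line meets the hull in more
than two points, the extremes along the line are used.

Shape measures divide the polygon area by the area of its minimum-area
enclosing triangle, rotated rectangle, or circle; all three lie in [0,1],
are scale-invariant, and equal 1 exactly when the polygon is its own
minimal enclosure.  The `shape` label is the argmax with the fixed tie
order triangular > rectangular > circular.  The enclosing rectangle and
circle come from shapely (`oriented_envelope`, `minimum_bounding_radius`);
the enclosing triangle is computed exactly by enumerating the support-line
configurations that can realise a local optimum — one side flush with a
hull edge, each remaining side flush with an edge or touching a hull
vertex at its midpoint — and minimising over all hull-containing
candidates (O(h³) with vectorised candidate batches; hulls here have tens
of vertices).  The configuration where both free sides satisfy the
midpoint condition simultaneously only arises as a degenerate family whose
endpoints coincide with flush configurations, so it needs no separate
case.

For a cluster: clusteredness = inverse mean pairwise centroid distance of
its members; density = mean grid value over the union of member pixels;
area/perimeter/distance/angle/shape/centroid are computed on the convex
hull of all member regions (holes between regions ignored).  Collections
of entities get clusteredness = inverse mean pairwise centroid distance
and density = mean member density divided by that mean distance.

Degenerate-input conventions (all keep the STML ranges intact): groups
with fewer than two members use divisor 1, so singleton clusteredness is
1; a hull degenerating to a segment has area 0 and perimeter twice its
length; area-0 polygons have shape measures 0, clusteredness 1 and
centroid at the vertex mean; identical member centroids (mean distance 0)
also fall back to clusteredness 1.

The Silhouette index over all member regions (dissimilarity =
centroid distance; singleton-cluster members contribute 0) is recorded per
timepoint as the numeric state variable `avgClusterednessClusters`.  With
fewer than two clusters, or with only singleton clusters, it is undefined
and no record is emitted; downstream comparisons on the missing variable
then evaluate false.

## Logic

Syntax is fixed in `docs/grammar.ebnf`.  Temporal bounds are relative to
the current evaluation state's time value and nest cumulatively: `F[a,b]ψ`
at state i (time tᵢ) holds iff ψ holds at some j ≥ i with tⱼ−tᵢ ∈ [a,b];
`G` is the dual; `ψ₁ U[a,b] ψ₂` requires ψ₂ at such a j with ψ₁ at all
states from i up to (excluding) j; `X[k]ψ` looks k states ahead.  A window
(or `d(·)`/`X[k]`) reaching past the trace end raises a trace-too-short
error — the trace provider must supply traces covering the formula
horizon.  Equality on reals means `|l − r| ≤ 1e-9`.

Two situations produce a *missing value* instead of an error, making the
innermost enclosing comparison false (and logging the event): a numeric
state variable absent from a state, and a non-count statistic over an
empty collection.  Entity collections are dynamic sets whose cardinality
changes over time, so emptiness is a normal state, not a fault.  The same
signal covers partial arithmetic: division by zero, square roots of
negatives, undefined powers.

Statistics: `percentile` uses the nearest-rank definition
(`rank = max(1, ⌈q/100·n⌉)`); `stdev` is the sample standard deviation (0
for fewer than two values); `mode` returns the smallest among the most
frequent values; `covariance` pairs the two collections by canonical
detection order, truncates to the shorter one (warning when cardinalities
differ), and needs at least two pairs.  `min`/`max` are statistics when
their first argument is a collection and binary arithmetic otherwise.
Filter constraints range over the eleven spatial measures only; state
variables, collections and temporal operators inside a filter are semantic
errors.  Oscillation properties are expressed by nesting `F` and `d`
(e.g. `F[a,b]((d(e) > 0) ^ F[1,b'](d(e) < 0))`); no dedicated operator is
added.  Evaluation is pure and memoised per (subformula, state) within a
call, which keeps deeply nested temporal formulas polynomial in practice.

## Probabilistic checking

A statement `P ⋈ θ [ψ]` is decided from the Bernoulli stream of ψ-values
on successive traces, consumed in canonical order (lexicographic file
names for a directory; invocation order for a generator script, whose
per-invocation seed is the master seed plus the invocation counter,
kept below 2³¹).

* **SPRT** (classical Wald form): H₀: p ≥ θ+δ vs H₁: p ≤ θ−δ with
  indifference half-width δ ∈ (0, min(θ, 1−θ)), default 0.05.  The
  log-likelihood ratio accumulates `ln(p₁/p₀)` per true and
  `ln((1−p₁)/(1−p₀))` per false observation; accept H₀ at
  `ln(β/(1−α))`, H₁ at `ln((1−β)/α)`.  H₀ makes ≥/> statements true, H₁
  makes </≤ true.  Statements with θ within δ of 0 or 1 require a
  narrower δ; the configuration is rejected otherwise rather than
  silently adjusted.
* **Chernoff–Hoeffding estimate**: fixed n = ⌈ln(c/δ)/(2ε²)⌉ with c = 2
  (the two-sided Hoeffding constant; some checkers use c = 4 — the
  constant is a config option), verdict `p̂ ⋈ θ`.
* **Bayes-factor test**: Beta(a,b) prior; B = posterior odds of
  {p : p ⋈ θ} over prior odds; decide true at B ≥ T, false at B ≤ 1/T
  (default T = 100).
* **Bayesian estimate**: posterior mean (a+x)/(a+b+n); stop when the
  posterior mass of (p̂−w, p̂+w) reaches the target coverage (checked
  after each observation, so at least one observation is always drawn).
* **Black box**: fixed sample; verdict `p̂ ⋈ θ` with ties resolved to the
  comparator's closed side (≥/≤ true, >/< false); confidence is the exact
  one-sided binomial tail probability under p = θ in the concluded
  direction.

Every sequential method falls back to the black-box verdict on the
observations gathered so far when the provider is exhausted (or the
trace/time budget is hit) before a decision; the result records the method
actually used and the exhaustion flag.  `check_specification` evaluates
all statements of a specification in one pass — each trace is loaded once
and fed to every still-undecided statement — and provably returns the same
results as per-statement runs over the same ordered provider, because each
statement consumes the same observation prefix either way.

## Synthetic case studies

The generators reproduce the qualitative phenomenology the shipped
specifications test, not the original simulators (a coloured stochastic
Petri net; a Cellular Potts model with a PDE attractant), which are out of
scope.  Both are bit-reproducible under a fixed seed.

**Colony (sectors).**  A 101×101 grid, a single wild-type founder at the
centre, radial colonisation at 1.25 lattice units per timepoint (40
timepoints by default, reaching the grid edge).  A newly colonised
position inherits the majority type of its occupied neighbours (random
ties) and switches type with probability 0.05 per division; an optional
cap limits wild-type→mutant seeding events.  Inheritance plus radial
growth turn switched lineages into angular wedges whose width grows with
radius — on the mutant-fraction grid these are detected as regions that
are typically more triangular than rectangular.  Occupied area is
non-decreasing; with switch probability 0 the mutant grid is identically
zero.

**Chemotaxis (clusters).**  A 100×100 lattice, 100 cells at distinct
random positions (1% occupancy), a static Gaussian attractant
(μ = (50,50), σ = 10 — the generator does not solve a PDE; a static field
suffices for the tested properties).  Per step a cell moves greedily
uphill with probability `attraction_strength` and takes a uniform
neighbour step otherwise; moves into positions at the pileup capacity
(default 3, the range visible in rendered snapshots of such simulations)
are blocked.  Without the capacity every walker stacks onto the single
peak cell and the cluster structure the specifications reason about
disappears.  Cell count is conserved; 200 steps suffice for full
aggregation at strength 1, while at strength 0 the mean distance to the
peak stays within a few percent of its initial value.

What passing tests on these generators do **not** show: fidelity of
mutation/fitness kinetics, volume exclusion beyond the pileup cap,
attractant dynamics, or any quantitative agreement with the original
benchmark datasets — only that the detection→measures→STML→logic→checking
chain draws the qualitatively correct conclusions (aggregation detected
under attraction and not under the null; sectors triangular) under
statistically controlled error.

## Problem sizes and defaults

Defaults mirror the benchmark conditions: 101×101 colony grids with 40
timepoints; 100×100 chemotaxis lattices, 100 cells, 201 timepoints;
α = β = 0.05, δ = 0.05, ε = δ_e = 0.05 (n = 738), T = 100, uniform prior.
The acceptance script uses 20 chemotaxis seeds per condition, 10 colony
seeds, and 200 Monte-Carlo repetitions for the operating-characteristic
rates; the test suite uses the same sizes (500 random formula/trace pairs
for the semantics oracle, 100 raster fixtures for the geometry oracles, 20
permutations of 50 regions for order invariance).

## Known limitations

Only pseudo-3D (no volumes or 3-D shapes) and a single spatial scale; no
tracking of entities across timepoints (each timepoint is analysed
independently); the STML dialect is this package's own — files from other
tools may use different element layouts; shape description is limited to
the three basic measures, which cannot separate composite patterns; the
area/perimeter of one-pixel-wide structures reflect the pixel-centre
polygon convention (a line of pixels has polygon area 0); silhouette-based
validity is undefined for a single cluster, which is common late in
aggregation runs.
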