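# Methods

## The screening model

`lcscreen` implements a triage rule for plant conservation assessment:
a species is *likely Least Concern* when four range statistics, computed
from occurrence records restricted to the species' native range, all meet
or exceed configurable thresholds. The rule is intentionally one-sided —
it is designed to pick out species that are safely non-threatened, not to
diagnose threat. Species failing any gauge, and species whose metrics
could not be computed, are simply returned to the expert-assessment
queue; nothing is ever published automatically, and bundle export
requires an explicit acceptance step because range statistics cannot see
range-wide declines (over-harvesting, disease, deforestation pressure
acting across the whole range).

### Name resolution

Queries are normalised to clean binomials (whitespace collapsed, genus
capitalised, infraspecific rank markers stripped and flagged). The
backbone returns scored candidates: exact case-insensitive equality gives
confidence 100 (EXACT); otherwise a sequence-similarity ratio ≥ 0.75
gives a FUZZY match with confidence 99 × ratio, strictly below any exact
match; genus-rank entries can supply a low-confidence HIGHERRANK
fallback, which is never assessed. Candidates are ordered by confidence,
then match-type rank, then name — fully deterministic on fixed backends.
In batch mode, names whose best match is a synonym are excluded (with the
accepted name surfaced for resubmission) rather than silently re-targeted
to a different taxon; in single mode the accepted name is followed by
default, with a strict mode that refuses instead. The asymmetry is
deliberate: a batch run is unattended, a single run has a user watching.

### Occurrence cleaning

Records must be georeferenced and free of the aggregator's geospatial
issue flag. Cleaning additionally removes non-finite and out-of-domain
coordinates, the (0, 0) "null island" artefact (user CSVs carry no issue
flags, so this common aggregator error is caught positionally), and
collapses exact duplicate (longitude, latitude) pairs — record counts are
defined on unique coordinates, with no rounding. When a backend holds
more records than the cap, the first `limit` records in backend order are
kept; a random subsample would make reruns irreproducible. The cap is
bounded to [1,000, 10,000] (default 3,000) — low enough to keep requests
tractable, high enough that widespread species still clear the
record-count gauge.

### Native-range filter

Point-in-polygon runs unprojected on lon/lat degrees, treating degrees as
planar. Level-3 units are large (small-to-medium countries), so planarity
errors are negligible at region scale; the store contract requires
antimeridian-crossing polygons to be pre-split into two lobes. Boundary
points count as inside (`covers`, not `contains`): excluding them could
only shrink the metrics and push a widespread species toward a false
threatened call, so inclusion is the precautionary choice.

### Projection

Areas must be in km², so each species' retained points are projected with
a Lambert cylindrical equal-area projection recentred on that species:
central meridian = mean longitude, standard parallel = mean latitude of
the points (clamped to ±89°), spherical Earth with R = 6371.0088 km. The
projection is exactly equal-area everywhere; recentring keeps shape
distortion small over a single species' extent. Species spanning the
antimeridian get a wrapped meridian offset; clouds genuinely straddling
±180° longitude are a known limitation of the arithmetic mean centre.

### EOO

The extent of occurrence is the area of the convex hull (minimum convex
polygon) of the unique projected points. Fewer than three distinct
points, or a collinear set (the hull degenerates to a segment), give
EOO = 0 with a warning rather than an error — and a warning always forces
the LC verdict to false.

### AOO

The area of occupancy is (number of occupied grid cells) × (cell area) on
a square grid of 10 km cells by default; one occupied cell is 100 km².
The 10-km cell deliberately coarsens the 2-km IUCN reference scale to
absorb unquantified georeference error in aggregated data; it is a
screening value only. **Grid anchoring:** the grid is anchored at the
south-west corner (min x, min y) of the projected point cloud. This makes
the cell count deterministic, invariant under translation and point
reordering, and guarantees that a cluster tighter than one cell width
occupies exactly one cell — so the documented single-cell worked value
(100 km²) holds identically rather than probabilistically. Anchoring at
the projection origin instead would place the recentred cloud's mean on a
cell edge, splitting every tight cluster across cells; a search over grid
offsets is deliberately not performed (determinism, and the screening
thresholds are far from the scale where offset optimisation matters).
The cell edge is exposed as a parameter (`cell_km`, CLI `--aoo-cell-km`).

### Counts and classification

RecordCount is the number of unique retained coordinate pairs; TDWGCount
is the number of *occupied* native Level-3 regions (regions with ≥ 1
retained point), not the length of the checklist's native list — the
statistic measures evidenced occupancy, and the alternative reading would
let a checklist entry with no data clear the gauge. Comparison against
thresholds is inclusive (metric ≥ threshold passes): "meets or exceeds"
is the operative rule, and the measure-zero boundary case is pinned by
tests. Defaults (EOO 30,000 km²; AOO 3,000 km²; 75 records; 5 regions)
follow the published guidance values for ranges unlikely to trigger a
threatened or Near Threatened category, chosen precautionarily — they sit
in the low-false-positive region of the calibration curves rather than at
peak accuracy. Thresholds must be strictly positive (a zero threshold
would make a gauge vacuous; degenerate-threshold experiments can use an
arbitrarily small positive value).

### Threshold calibration

Sweeps are per-parameter: at each grid value the prediction is positive
iff the swept metric alone meets the candidate threshold, the other three
being ignored — matching how per-parameter calibration curves are read.
Truth classes: LC is positive; NT, VU, EN, CR are negative (the screen's
purpose is isolating LC from everything of elevated concern, so Near
Threatened is grouped with threatened); DD, NE and non-extant categories
(EX, EW) are excluded. Accuracy = (TP+TN)/total, TPR = TP/(TP+FN),
FPR = FP/(FP+TN), reported as None when a truth class is empty. The
false-positive rate does not reach zero on realistic data: a wide-ranging
species threatened by range-wide pressure exceeds every candidate
threshold, which is exactly why acceptance remains a human decision.

### Assessment bundles

Seven cross-linked CSV tables (allfields, assessments, countries,
credits, habitats, plantspecific, taxonomy) keyed by a sequential
`internal_taxon_id`, plus a point-distribution CSV carrying the
map-standard presence/origin/seasonality attributes (extant / native /
resident by default). The exchange format's exact column sets are not
published as a frozen schema, so they live in a versioned config
(`data/sis_schema.json`); operators tracking the current upstream
requirements edit the config, not the code. Non-computable fields use
overridable defaults: category "LC", population trend "Unknown", habitat
18 "Unknown", terrestrial system, auto-cited data-source bibliography.
Countries rows derive from native Level-3 codes through a bundled
code→country table (a subset; unknown codes fall back to the code itself
so nothing is dropped silently). All cell values are stored as strings,
making write/read round trips exact; `validate_bundle` checks referential
closure, one-row-per-taxon discipline and the LC category.

## Synthetic data

The generators define the test conditions and are first-class code:

* **Occurrence clouds** are isotropic Gaussians with dispersion in
  projected km (not degrees), so expected footprints — and hence expected
  AOO/EOO — are latitude-independent. Deterministic under seed.
* **Toy region grids** are non-overlapping lon/lat rectangles with
  3-letter codes, written/read as the same GeoJSON dialect as real
  Level-3 stores.
* **Validation tables** draw the four metrics as independent lognormals
  around per-class medians (LC: EOO 5×10⁵ km², AOO 2×10⁴ km², 500
  records, 12 regions; threatened: 8×10³ km², 600 km², 20 records, 2
  regions; log-space σ = 1.0 — medians chosen so the classes overlap but
  separate at screening scale, i.e. the effect size of each metric is the
  log-ratio of its class medians). Counts are floored at 1 and AOO is
  clamped to its feasible band [cell area, records × cell area]. Planted
  outliers are deterministic wide-ranging threatened species whose
  metrics exceed any plausible grid value.

What the synthetic world does **not** emulate: spatial sampling bias,
duplicated specimens from single populations, correlated metrics,
georeference error, or real region outlines. Passing tests therefore
demonstrate the correctness of the computations and the bookkeeping, not
the field accuracy of the thresholds on real floras.

## Numerical and testing choices

* Hull area via the projected convex hull; verified against an
  independent O(n³) hull-edge enumeration + shoelace oracle to 10⁻⁶
  relative on random instances.
* Native-filter retention verified against an even–odd ray-casting oracle
  with explicit on-segment handling.
* Sweep tallies verified against a naive per-record loop (1,000 records ×
  50-point grid in tests).
* Bundle round trips exercised on hundreds of randomised bundles.
* Test problem sizes (≤ 200 random geometry instances, ≤ 100 points per
  hull, ~1,000-record sweeps, 500 bundles) were chosen as the smallest
  sizes at which the oracles meaningfully constrain the implementation;
  the full suite runs in a few seconds.

## Known limitations

* Arithmetic-mean projection centre misbehaves for point clouds
  straddling the antimeridian.
* The fuzzy matcher is a similarity ratio, not a nomenclature-aware
  parser; authority strings are stored, never parsed.
* The bundled Level-3→country table covers a subset of codes; unknown
  codes pass through as-is and should be reconciled by the operator.
* Live HTTP clients are thin conveniences: unversioned upstream APIs,
  no rate-limit handling beyond a single request timeout, and no tests.
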