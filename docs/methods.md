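# Methods

## Model of the problem

Two co-registered categorical rasters describe the same landscape from
different thematic angles. The vegetation layer maps natural and semi-natural
vegetation in detail but collapses agriculture into ~10 broad groups, each
present as several geographic (Western/Eastern) and climatic (Cool/Warm)
variant codes. The crop layer maps agriculture as specific crop types but is
coarse on everything else. The merge keeps the vegetation layer everywhere it
is non-agricultural and replaces its agricultural pixels with crop identity
from the crop layer, using a single signed-integer code space: vegetation
codes unchanged (positive), crop codes negated, and −1001 for agricultural
pixels whose conflict could not be resolved.

The central modelling object is the class-match table. A crop value c is
considered *consistent* with vegetation group g when c is a synonym (wheat ~
wheat), a subset (orchard ⊃ apples, cherries, …), or a rotation partner:
because one vegetation snapshot is combined with many crop years, a row-crop
pixel may legitimately read corn one year and soybeans or alfalfa the next.
Six broad groups (row crop, close-grown crop, their combination, fallow/idle,
pasture/hayland, wheat) therefore share one pooled ~90-crop match set. The
packaged table lists, per group, its variant codes and match set; three of
the orchard crop names in the published listing have no printed codes, so all
names are resolved through a packaged crop-legend registry (name → code) that
is validated against every code that *is* printed.

A pixel pair is then PASSTHROUGH (vegetation not agricultural — including
developed classes, which are retained, and vegetation nodata), MATCHED
(c ∈ M(g)), or MISMATCHED (everything else; crop-layer nodata or
non-agricultural values at an agricultural vegetation pixel are conflicts,
not errors). This classification is total: every integer pair falls in
exactly one class, which the property tests assert.

## Conflict resolution

Each mismatched pixel receives the negated modal crop code among *eligible
donors* within Chebyshev radius r = 3 (a 7×7 window; 90 m at 30 m cells), or
−1001 when the window holds none. Choices that the published description
leaves open, and how this package fixes them:

* **Donor eligibility** defaults to pixels that MATCHED in step 1
  (`matched_only`). The alternative reading — any pixel whose crop value is
  agricultural — cannot produce the documented behaviour of whole fields
  staying unresolved when the crop layer calls them a *different* kind of
  agriculture (orchard over grass/pasture), so the stricter policy is the
  default and `any_cdl_ag` is a config option. Under both policies the focal
  pixel never donates to itself.
* **Window shape** is the square 7×7 window, treating "3-pixel radius" as
  Chebyshev distance; the window is truncated at the grid boundary
  (out-of-grid cells contribute no donors).
* **Ties** in the mode break to the smallest crop code — deterministic and
  platform-independent.
* **Simultaneity.** Donor state is frozen at step 1; resolved pixels never
  become donors. This makes resolution order-independent and idempotent, and
  is what guarantees exact tiled/monolithic equivalence.

The implementation counts donors per candidate code with a 7×7 box filter
(`scipy.ndimage.correlate`) over donor-indicator rasters, scanning candidate
codes in ascending order with a strict-improvement rule so the smallest code
wins ties. Tests compare it against an independent per-pixel
window-enumeration oracle on small grids.

## Tiling

`plan_tiles` lays out square core windows row-major from the grid origin
(side = ⌊√(target area)/cell size⌋ pixels, default target 1000 km² → 1054 px
at 30 m; trailing tiles smaller), each padded by `overlap` pixels and clipped
to the grid. The plan is rejected unless overlap ≥ merge radius. Each padded
tile is merged independently and only the core written back; because the
merge is a pure function of the 7×7 neighbourhood, the mosaic is bit-identical
to the monolithic result — asserted, not assumed, by the equivalence tests,
including fixtures with conflicts planted exactly on tile seams.

## Zonal statistics

Zone membership is by zone-raster pixel value (the zone raster is an input,
making the polygon-to-pixel rule explicit). Percent denominators differ by
product on purpose: mismatch percentages divide by the zone's pixel count of
the focal vegetation *group* (share of that group's area in conflict);
unresolved percentages divide by the zone's *total* pixel count (share of
zone area). Zero-denominator groups emit no row rather than dividing by zero.

Weighted accuracy integrates published per-class user's/producer's accuracy
of the source layers: for a merged raster, negative codes draw from the
crop-layer records, non-negative codes from the vegetation records, weighted
by class pixel counts. Classes without reference data — and classes whose
reference flag is set but carry no usable accuracy values — are excluded
from the means *and* from the with-reference area, because published
accuracy and reference coverage are two views of the same underlying data
availability. Coverage is reported as `WithData_Pct` = 100 × with-reference
area / focal area; unresolved pixels are excluded from the focal area
entirely.

Jenks natural breaks are computed exactly by Fisher's dynamic programming
over the sorted values (O(k·n²)), not by the common heuristic reseating
variant; `jenks_objective` exposes the minimized within-class sum of squares
so optimality is testable against an exhaustive partition search. Requesting
more classes than distinct values is an error.

## Synthetic landscapes

`generate_pair` tessellates the grid into axis-aligned rectangular fields
(default 10×10 px), marks each agricultural with probability `ag_fraction`
(default 0.6), assigns agricultural fields a uniformly drawn group and
variant, natural fields a synthetic natural code (6001–6006, occasionally a
developed code 7296–7299), and grows a per-year crop drawn from the field's
match set (rotation inside the match set — deliberately conflict-free).
Conflicts are planted three ways, mirroring the phenomena the merge must
handle: scattered pixels flipped to a conflicting value (`conflict_rate`,
default 4% of agricultural pixels; half to non-agricultural covers, half to
agricultural codes outside the focal match set), additional isolated noise
pixels flipped to out-of-set crops (`noise_rate`, default 1.5%), and
`whole_field_conflict_count` entire fields (default 1) overwritten with a
non-agricultural cover. The defaults put roughly 5–6% of agricultural pixels
in conflict, the disagreement level typical of the real products. Zones are
horizontal bands with FIPS-like codes.

Ground truth is computed from the finished grids by direct per-pixel set
membership, and unresolvability by a per-pixel window scan for matched
donors — both independent of the merge engine's vectorised code paths — so
"planted-truth recovery" tests compare two separate derivations of the same
quantities.

What the generator does **not** emulate: spatial autocorrelation of natural
vegetation, realistic field-size distributions, classifier error structure of
the source products, or polygon-based (rather than raster-band) counties.
Passing tests therefore demonstrate correctness of the merge/statistics
machinery on structured categorical rasters, not classification quality on
real imagery-derived data.

## Numerical and I/O choices

* Output dtype is int32: codes span −1001 to ~7999, and 32 bits leaves slack
  for future legends.
* GeoTIFF support is a deliberately small layer over `tifffile`, reading and
  writing the pixel-scale, tiepoint, GeoKey (EPSG) and GDAL-nodata tags —
  sufficient for lossless single-band categorical round-trips, which the
  tests verify on disk. Only EPSG-coded CRSs are supported; files are written
  uncompressed by default (a `compression` argument is exposed). TIFF
  palettes only exist for unsigned 8/16-bit samples, so the color map ships
  as the sidecar attribute CSV (the published form) instead of an embedded
  palette.
* The attribute table for a merged raster is vegetation rows unchanged, crop
  rows re-emitted with negated codes, plus exactly one row for −1001;
  duplicate values or missing source rows are hard errors.
* Degenerate inputs: empty grids, non-integer rasters, non-positive cell
  sizes, misaligned pairs (shape, geotransform or CRS) and overlap < radius
  are all rejected with specific errors; nothing is ever resampled silently.

## Problem sizes used in the shipped checks

Fixtures run at 64–512 px squares (tiled-equivalence), ≤15 px squares
(oracle agreement, 50 seeds), and 96 px squares × 10 seeds × 3 years
(planted-truth recovery) — sizes chosen so the full suite exercises every
path, including two 512×512 tiled runs, while remaining quick on one CPU.
The machinery itself is linear in pixel count × candidate donor codes and is
routinely run at much larger extents via the tiling module.

## Known limitations

* The matched-donor default is a reconstruction of underdocumented behaviour;
  analyses sensitive to the choice should run both policies and compare.
* Accuracy integration assumes per-class accuracies are exchangeable across
  zones (the published statistics are per state/region, not per county); the
  area weighting is exact, the inputs are as coarse as their sources.
* The state-buffering step used for production-scale processing of real
  national rasters (clipping to buffered state polygons before tiling) is out
  of scope: grids handed to `plan_tiles` are assumed already clipped.
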