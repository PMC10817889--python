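# spanmerge

Fuse two co-registered categorical land-cover rasters — a natural-vegetation
map with broad agricultural classes (NVC-style) and an annual crop-type map
(CDL-style) — into a single integrated product that is detailed on both the
natural and the agricultural side. The package is for landscape ecologists
and geospatial analysts who need crop identity *and* fine-grained natural
vegetation in one layer, e.g. as input to pollination, pest-dynamics or
carbon models.

## The method

Only agricultural pixels of the vegetation layer are touched; natural,
developed and nodata pixels pass through bit-identically.

1. **Reclassify.** A class-match table maps each vegetation agricultural
   group g (Vineyard, Orchard, Row Crop, …; each group appears as several
   geographic/climatic variant codes) to the set M(g) of crop codes
   consistent with it — synonyms, subsets, or crop-rotation partners. For a
   pixel with vegetation group g and crop value c: if c ∈ M(g) the pixel
   becomes −c (crop codes are negated so they cannot collide with vegetation
   codes); otherwise the pixel is *mismatched*.
2. **Resolve.** Each mismatched pixel takes −(modal crop code) among eligible
   donor pixels within a 7×7 window (Chebyshev radius r = 3, i.e. 90 m at
   30 m cells), ties to the smallest code. Donors are the pixels that
   *matched in step 1* (default policy; a policy admitting any agricultural
   crop pixel is available). If the window holds no donor the pixel gets the
   sentinel **−1001**, unresolved land cover.

Donor eligibility is frozen at the step-1 state, so resolution is a single
simultaneous pass: order-independent, idempotent, and exactly equivalent
under tiling. Large extents are processed as ~1000 km² tiles padded by the
merge radius; the tiled mosaic is bit-identical to a monolithic run
(`merge_tiled` vs `merge`, property-tested).

Validation statistics mirror the published tabular products: per-zone
(county-like) mismatch accounting by vegetation group × conflicting crop
class, per-zone unresolved percentages, area-weighted mean user's/producer's
accuracy integrating the source layers' published per-class accuracies
(classes without reference data are excluded and reported as a coverage
percentage), and exact Jenks natural breaks (Fisher's dynamic programming)
for mapping the percentages as discrete intervals.

## Worked example

```python
import numpy as np
from spanmerge import CategoricalGrid, default_match_table, merge

table = default_match_table()
nvc = np.full((12, 12), 6001, dtype=np.int32)   # natural vegetation
nvc[2:8, 1:6] = 7964                            # row-crop field
nvc[2:8, 7:11] = 7961                           # vineyard field
cdl = np.full((12, 12), 152, dtype=np.int32)    # shrubland in the crop layer
cdl[2:8, 1:6] = 1                               # corn (matches row crop)
cdl[2:8, 7:11] = 69                             # grapes (matches vineyard)
cdl[4, 8] = 1                                   # noise pixel inside the vineyard

result = merge(CategoricalGrid(values=nvc), CategoricalGrid(values=cdl), table)
print(result.counts)
print(result.merged.values[4, 8])
```

prints

```
{'passthrough': 90, 'matched': 53, 'mismatched': 1, 'resolved': 1, 'unresolved': 0}
-69
```

90 natural pixels pass through, 53 agricultural pixels match and take their
negated crop code (−1 corn, −69 grapes), and the corn noise pixel inside the
vineyard conflicts with the vineyard group but is resolved back to grapes
(−69) by the 7×7 modal-donor rule. The `examples/` scripts walk through the
other capabilities: unresolved whole fields under the matched-donor policy,
tiled processing, and the zonal statistics.

A thin CLI wraps the same functions:

```sh
spanmerge synth --rows 128 --cols 128 --seed 4 --out fix/
spanmerge merge --nvc fix/nvc.tif --cdl fix/cdl_2016.tif --year 2016 --out out/
spanmerge stats --nvc fix/nvc.tif --cdl fix/cdl_2016.tif --zones fix/zones.tif \
    --year 2016 --out out/
spanmerge verify --raster out/span_2016.tif --attribute-table attrs.csv
```

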