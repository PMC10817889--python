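"""Zonal agreement and accuracy statistics on a synthetic landscape.

Generates a landscape with known planted conflicts, merges it, then computes
the per-zone mismatch table, the unresolved table, a county-style weighted
accuracy integration, and Jenks natural breaks for mapping the percentages.
"""

import numpy as np

from spanmerge import (
    FixtureSpec, default_match_table, generate_accuracy_records, generate_pair,
    jenks_breaks, merge, mismatch_stats, span_accuracy, unresolved_stats,
)

table = default_match_table()
pair = generate_pair(FixtureSpec(rows=128, cols=128, seed=11, n_zones=4), table)
cdl = pair.cdl_by_year[2016]
res = merge(pair.nvc, cdl, table)

mism = mismatch_stats(pair.nvc, cdl, pair.zones, table, year=2016)
unres = unresolved_stats(res, pair.zones, year=2016)

print("mismatch rows:", len(mism))
top = mism.sort_values("NCells_Mismatch", ascending=False).head(3)
print(top[["FIPS", "NVC_Name", "CDL_Name", "NCells_Mismatch", "Pct_Mismatch"]]
      .to_string(index=False))
print("\nunresolved per zone:")
print(unres[["FIPS", "NCells", "Pct_Unresolved"]].to_string(index=False))

# accuracy integration: synthetic published accuracies for every class in the
# merged raster, split into crop-layer (negative codes) and vegetation records
merged_codes = np.unique(res.merged.values)
crop_classes = sorted(-c for c in merged_codes if c < 0 and c != -1001)
veg_classes = sorted(int(c) for c in merged_codes if c >= 0)
cdl_recs = generate_accuracy_records(crop_classes, seed=1)
nvc_recs = generate_accuracy_records(veg_classes, seed=2, frac_without_reference=0.3)

acc = span_accuracy(res.merged, pair.zones, cdl_recs, nvc_recs, year=2016)
print("\nweighted accuracy per zone:")
print(acc[["FIPS", "WithData_PctFocalGroup", "WtdUserAcc", "WtdProdAcc"]]
      .round(1).to_string(index=False))

pcts = mism["Pct_Mismatch"].tolist()
print("\nJenks class edges for mismatch percentages (k=3):",
      [round(e, 2) for e in jenks_breaks(pcts, 3)])
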