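"""Merge a small hand-built landscape and inspect the conflict accounting.

Builds a 12x12 vegetation grid (natural land, a row-crop field, a vineyard
field), a crop grid that agrees except where we plant conflicts, and runs the
two-step merge.
"""

import numpy as np

from spanmerge import CategoricalGrid, MergeConfig, default_match_table, merge

table = default_match_table()

nvc = np.full((12, 12), 6001, dtype=np.int32)   # natural vegetation
nvc[2:8, 1:6] = 7964                            # row-crop field
nvc[2:8, 7:11] = 7961                           # vineyard field

cdl = np.full((12, 12), 152, dtype=np.int32)    # shrubland in the crop layer
cdl[2:8, 1:6] = 1                               # corn: matches row crop
cdl[2:8, 7:11] = 69                             # grapes: matches vineyard
cdl[4, 8] = 1                                   # noise pixel: corn inside vineyard
cdl[5, 9] = 152                                 # noise pixel: shrubland inside vineyard

result = merge(CategoricalGrid(values=nvc), CategoricalGrid(values=cdl), table)

print("counts:", result.counts)
print("noise pixel (4,8)  ->", result.merged.values[4, 8])
print("noise pixel (5,9)  ->", result.merged.values[5, 9])
print("natural pixel (0,0)->", result.merged.values[0, 0])

# Matched pixels carry negated crop codes (-1 corn, -69 grapes); both noise
# pixels conflict with the vineyard group but are surrounded by matched grape
# pixels, so the 7x7 modal-donor rule resolves them back to -69. Natural
# pixels pass through untouched.
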