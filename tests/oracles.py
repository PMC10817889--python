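"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementation: the merge oracle
enumerates each pixel's window with Python loops and per-pixel
classification; the Jenks oracle searches every contiguous partition of the
sorted values.
"""

from __future__ import annotations

import itertools

import numpy as np

from spanmerge.taxonomy import ClassMatchTable, Relation, classify_pair


def oracle_merge(
    nvc: np.ndarray,
    cdl: np.ndarray,
    table: ClassMatchTable,
    radius: int = 3,
    donor_policy: str = "matched_only",
    unresolved_code: int = -1001,
) -> np.ndarray:
    """Exhaustive per-pixel two-step merge by direct window enumeration."""
    rows, cols = nvc.shape
    rel = [
        [classify_pair(int(nvc[r, c]), int(cdl[r, c]), table) for c in range(cols)]
        for r in range(rows)
    ]
    out = np.empty((rows, cols), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            if rel[r][c] is Relation.PASSTHROUGH:
                out[r, c] = nvc[r, c]
            elif rel[r][c] is Relation.MATCHED:
                out[r, c] = -cdl[r, c]
            else:
                votes: dict[int, int] = {}
                for rr in range(max(0, r - radius), min(rows, r + radius + 1)):
                    for cc in range(max(0, c - radius), min(cols, c + radius + 1)):
                        if (rr, cc) == (r, c):
                            continue
                        if donor_policy == "matched_only":
                            eligible = rel[rr][cc] is Relation.MATCHED
                        else:
                            eligible = int(cdl[rr, cc]) in table.cdl_ag_set
                        if eligible:
                            code = int(cdl[rr, cc])
                            votes[code] = votes.get(code, 0) + 1
                if votes:
                    # modal code; ties to the smallest code
                    best = min(votes, key=lambda k: (-votes[k], k))
                    out[r, c] = -best
                else:
                    out[r, c] = unresolved_code
    return out


def oracle_jenks_cost(values, k: int) -> float:
    """Minimal total within-class SSD over all contiguous partitions of the
    sorted values into k nonempty classes, by exhaustive search."""
    vals = sorted(float(v) for v in values)
    n = len(vals)

    def ssd(chunk) -> float:
        m = sum(chunk) / len(chunk)
        return sum((x - m) ** 2 for x in chunk)

    best = float("inf")
    for splits in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        cost = sum(ssd(vals[bounds[i]:bounds[i + 1]]) for i in range(k))
        best = min(best, cost)
    return best


def partition_cost(values, edges) -> float:
    """Total within-class SSD of sorted values classified by Jenks edges."""
    vals = np.sort(np.asarray(values, dtype=float))
    idx = np.searchsorted(np.asarray(edges[1:-1]), vals, side="left")
    cost = 0.0
    for cls in np.unique(idx):
        chunk = vals[idx == cls]
        cost += float(((chunk - chunk.mean()) ** 2).sum())
    return cost
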