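"""Two-step merge of a crop raster into the agricultural pixels of a
vegetation raster.

Step 1 reclassifies: pixels that are agricultural in the vegetation layer and
carry a crop code from their group's match set receive the negated crop code;
non-agricultural vegetation passes through untouched; the remaining
agricultural pixels are *mismatched* — the crop layer disagrees with the
vegetation group there.

Step 2 resolves: each mismatched pixel takes the modal crop code among
*eligible donor* pixels within a square window of Chebyshev radius ``radius``
(default 3, i.e. a 7×7 window, 90 m at 30 m cells), the focal pixel excluded.
A pixel with no eligible donor in its window receives the unresolved sentinel
(−1001 by default).  Donor eligibility is fixed by the step-1 state — resolved
pixels never become donors — so resolution is a single simultaneous pass:
order-independent, idempotent, and exactly equivalent under tiling with
sufficient overlap.

Donor policy is configurable.  Under ``matched_only`` (default), only pixels
that MATCHED in step 1 may donate; this reproduces the observed behaviour of
whole conflicting fields staying unresolved even when the crop layer calls
them (a different kind of) agriculture.  Under ``any_cdl_ag`` any pixel whose
crop-layer value is agricultural may donate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grid import AlignmentError, CategoricalGrid
from .taxonomy import ClassMatchTable, MergedCodeScheme, Relation

__all__ = ["MergeConfig", "MergeResult", "merge_step1", "resolve_step2", "merge",
           "merge_annual_series", "relation_grids"]

_DONOR_POLICIES = ("matched_only", "any_cdl_ag")
_TIE_BREAKS = ("smallest_code",)


@dataclass(frozen=True)
class MergeConfig:
    """Conflict-resolution parameters.

    radius : Chebyshev search radius in pixels; the window side is
        ``2*radius + 1`` (default 3 → 7×7 ≈ 90 m at 30 m cells).
    donor_policy : ``matched_only`` or ``any_cdl_ag`` (see module docstring).
    tie_break : modal-tie rule; ``smallest_code`` is deterministic and
        platform-independent.
    unresolved_code : sentinel written when no donor exists.
    """

    radius: int = 3
    donor_policy: str = "matched_only"
    tie_break: str = "smallest_code"
    unresolved_code: int = -1001

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.donor_policy not in _DONOR_POLICIES:
            raise ValueError(f"donor_policy must be one of {_DONOR_POLICIES}")
        if self.tie_break not in _TIE_BREAKS:
            raise ValueError(f"tie_break must be one of {_TIE_BREAKS}")

    @property
    def window_side(self) -> int:
        return 2 * self.radius + 1


@dataclass
class MergeResult:
    """Merged grid plus the conflict accounting masks and counts.

    ``mismatch_mask`` marks step-1 conflicts (before resolution);
    ``unresolved_mask`` marks the subset that no donor could resolve.
    ``counts`` holds {passthrough, matched, mismatched, resolved, unresolved};
    invariants: matched + mismatched = number of agricultural vegetation
    pixels, resolved + unresolved = mismatched.
    """

    merged: CategoricalGrid
    mismatch_mask: np.ndarray
    unresolved_mask: np.ndarray
    counts: dict[str, int]
    resolved_step2: bool = False

    def check_accounting(self) -> None:
        c = self.counts
        n = self.merged.values.size
        if c["matched"] + c["mismatched"] + c["passthrough"] != n:
            raise AssertionError("pixel accounting does not cover the grid")
        if self.resolved_step2 and c["resolved"] + c["unresolved"] != c["mismatched"]:
            raise AssertionError("resolved + unresolved != mismatched")
        if int(self.mismatch_mask.sum()) != c["mismatched"]:
            raise AssertionError("mismatch mask inconsistent with counts")
        if int(self.unresolved_mask.sum()) != c["unresolved"]:
            raise AssertionError("unresolved mask inconsistent with counts")


def relation_grids(
    nvc: CategoricalGrid, cdl: CategoricalGrid, table: ClassMatchTable
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pixel classification.

    Returns ``(ag_mask, matched_mask)``: where the vegetation value is
    agricultural, and where additionally the crop value lies in that group's
    match set.  Mismatched = ag & ~matched; passthrough = ~ag.
    """
    nvc_v = nvc.values
    cdl_v = cdl.values
    ag = np.isin(nvc_v, list(table.nvc_ag_set))
    matched = np.zeros(nvc_v.shape, dtype=bool)
    for group in table.groups:
        in_group = np.isin(nvc_v, list(group.nvc_values))
        if in_group.any():
            matched |= in_group & np.isin(cdl_v, list(group.cdl_values))
    return ag, matched


def merge_step1(
    nvc: CategoricalGrid,
    cdl: CategoricalGrid,
    table: ClassMatchTable,
    scheme: MergedCodeScheme | None = None,
) -> MergeResult:
    """Reclassify matched agricultural pixels to negated crop codes.

    Passthrough pixels copy the vegetation value (including its nodata);
    matched pixels get the negated crop code; mismatched pixels keep the
    vegetation value as a placeholder and are flagged in ``mismatch_mask``.
    Inputs must be exactly aligned; nothing is resampled.
    """
    scheme = scheme or MergedCodeScheme()
    scheme.validate(table)
    nvc.check_aligned(cdl, "crop grid")

    ag, matched = relation_grids(nvc, cdl, table)
    mismatched = ag & ~matched

    out = nvc.values.astype(np.int32, copy=True)
    out[matched] = -cdl.values[matched].astype(np.int32)

    counts = {
        "passthrough": int((~ag).sum()),
        "matched": int(matched.sum()),
        "mismatched": int(mismatched.sum()),
        "resolved": 0,
        "unresolved": 0,
    }
    return MergeResult(
        merged=nvc.like(out),
        mismatch_mask=mismatched,
        unresolved_mask=np.zeros_like(mismatched),
        counts=counts,
    )


def _window_counts(indicator: np.ndarray, radius: int) -> np.ndarray:
    """Count of True cells of *indicator* within Chebyshev distance <= radius
    of each pixel (window truncated at the grid boundary)."""
    kernel = np.ones((2 * radius + 1, 2 * radius + 1), dtype=np.int64)
    return ndimage.correlate(
        indicator.astype(np.int64), kernel, mode="constant", cval=0
    )


def resolve_step2(
    step1: MergeResult,
    cdl: CategoricalGrid,
    table: ClassMatchTable,
    config: MergeConfig | None = None,
) -> MergeResult:
    """Assign each mismatched pixel the modal eligible-donor crop code within
    the search window, or the unresolved sentinel when no donor exists.

    Donors are fixed from the step-1 state: under ``matched_only`` the pixels
    flagged MATCHED in step 1 (the focal pixel, being mismatched, can never
    donate to itself); under ``any_cdl_ag`` any pixel with an agricultural
    crop-layer value, the focal pixel explicitly excluded.  Modal ties break
    to the smallest crop code.
    """
    config = config or MergeConfig()
    step1.merged.check_aligned(cdl, "crop grid")

    mismatched = step1.mismatch_mask
    out = step1.merged.values.copy()
    unresolved = np.zeros_like(mismatched)

    if mismatched.any():
        ag_codes = list(table.cdl_ag_set)
        if config.donor_policy == "matched_only":
            donor_mask = ~mismatched & np.isin(
                step1.merged.values, [-c for c in ag_codes]
            )
        else:
            donor_mask = np.isin(cdl.values, ag_codes)

        best_count = np.zeros(mismatched.shape, dtype=np.int64)
        best_code = np.full(mismatched.shape, config.unresolved_code, dtype=np.int32)
        donor_codes = np.unique(cdl.values[donor_mask]) if donor_mask.any() else []
        # ascending code order + strict > : modal ties break to the smallest code
        for code in donor_codes:
            counts = _window_counts(donor_mask & (cdl.values == code), config.radius)
            if config.donor_policy == "any_cdl_ag":
                # window sums include the focal cell; subtract its own donorship
                counts = counts - (donor_mask & (cdl.values == code)).astype(np.int64)
            better = mismatched & (counts > best_count)
            best_count[better] = counts[better]
            best_code[better] = -int(code)

        out[mismatched] = best_code[mismatched]
        unresolved = mismatched & (best_count == 0)

    counts = dict(step1.counts)
    counts["unresolved"] = int(unresolved.sum())
    counts["resolved"] = counts["mismatched"] - counts["unresolved"]
    return MergeResult(
        merged=step1.merged.like(out),
        mismatch_mask=mismatched,
        unresolved_mask=unresolved,
        counts=counts,
        resolved_step2=True,
    )


def merge(
    nvc: CategoricalGrid,
    cdl: CategoricalGrid,
    table: ClassMatchTable,
    scheme: MergedCodeScheme | None = None,
    config: MergeConfig | None = None,
) -> MergeResult:
    """Full two-step merge (reclassify, then resolve).  Deterministic."""
    config = config or MergeConfig()
    scheme = scheme or MergedCodeScheme(unresolved_code=config.unresolved_code)
    step1 = merge_step1(nvc, cdl, table, scheme)
    return resolve_step2(step1, cdl, table, config)


def merge_annual_series(
    nvc: CategoricalGrid,
    cdl_by_year: Mapping[int, CategoricalGrid],
    table: ClassMatchTable,
    scheme: MergedCodeScheme | None = None,
    config: MergeConfig | None = None,
) -> dict[int, MergeResult]:
    """One independent merge per crop-layer year against the single
    vegetation layer; passthrough pixels are identical across years."""
    for year, cdl in cdl_by_year.items():
        try:
            nvc.check_aligned(cdl, "crop grid")
        except AlignmentError as exc:
            raise AlignmentError(f"year {year}: {exc}") from None
    return {
        year: merge(nvc, cdl, table, scheme, config)
        for year, cdl in sorted(cdl_by_year.items())
    }
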