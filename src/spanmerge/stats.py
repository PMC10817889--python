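"""Agreement and accuracy statistics for the merged land-cover product.

Four products, mirroring the tabular outputs published alongside the merged
rasters:

* per-zone (county-like) counts and percentages of *mismatched* pixels after
  merge step 1, broken down by vegetation group × conflicting crop class;
* per-zone counts and percentages of *unresolved* pixels in the final raster;
* per-zone area-weighted mean user's/producer's accuracy, integrating
  published per-class accuracy of the two source layers, plus the fraction of
  the focal area whose classes have reference data at all;
* Jenks natural-breaks discretization (exact dynamic-programming optimal
  1-D classification) used to bin percentages for mapping.

Plus an automated output check (extent, CRS, pixel values against the
attribute table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import CategoricalGrid
from .merge import MergeResult, relation_grids
from .taxonomy import (
    AttributeRow,
    ClassMatchTable,
    MergedCodeScheme,
    UNRESOLVED_NAME,
    cdl_name_registry,
)

__all__ = [
    "AccuracyRecord",
    "MISMATCH_COLUMNS",
    "UNRESOLVED_COLUMNS",
    "ACCURACY_COLUMNS",
    "mismatch_stats",
    "unresolved_stats",
    "weighted_accuracy",
    "span_accuracy",
    "jenks_breaks",
    "jenks_objective",
    "jenks_assign",
    "VerificationReport",
    "verify_output",
]

MISMATCH_COLUMNS = [
    "FIPS", "State", "CDL_Year", "CDL_Class", "CDL_Name", "NVC_Name",
    "NCells_Mismatch", "NCells_NVCClass_perCounty", "NVC_CDL_Pair", "Pct_Mismatch",
]
UNRESOLVED_COLUMNS = [
    "FIPS", "State", "CDL_Year", "County", "LF2010_Region",
    "MergedRaster_Class", "MergedRaster_ClassName", "NCells", "Pct_Unresolved",
]
ACCURACY_COLUMNS = [
    "FIPS", "State", "CDL_Year", "County", "FocalGroup", "Dataset_Name",
    "NCells_County", "NCells_FocalGroup", "FocalGroup_PctCounty",
    "WithData_PctFocalGroup", "WtdProdAcc", "WtdUserAcc",
]


@dataclass(frozen=True)
class AccuracyRecord:
    """Published per-class accuracy for one land-cover class.

    ``has_reference`` is False for classes absent from the reference data
    (e.g. vegetation types with fewer than 30 surveyed field plots); such
    classes carry no accuracy values and are excluded from weighted means.
    """

    class_value: int
    users_acc: float | None = None
    producers_acc: float | None = None
    has_reference: bool = True

    def __post_init__(self) -> None:
        if not self.has_reference and (
            self.users_acc is not None or self.producers_acc is not None
        ):
            raise ValueError("class without reference data cannot carry accuracies")
        for a in (self.users_acc, self.producers_acc):
            if a is not None and not 0 <= a <= 100:
                raise ValueError(f"accuracy {a} outside [0, 100]")


def _zone_values(zones: CategoricalGrid) -> np.ndarray:
    vals = np.unique(zones.values)
    return vals[vals != zones.nodata]


def mismatch_stats(
    nvc: CategoricalGrid,
    cdl: CategoricalGrid,
    zones: CategoricalGrid,
    table: ClassMatchTable,
    year: int,
    state_by_zone: Mapping[int, str] | None = None,
    cdl_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Step-1 conflict accounting per zone × vegetation group × crop class.

    One row per (zone, vegetation group, conflicting crop class) with a
    nonzero mismatch count.  Vegetation variant codes are pooled to their
    group name (dropping geographic/climatic qualifiers).  The percentage
    denominator is the zone's pixel count of that vegetation group, so
    ``Pct_Mismatch`` reads "share of this group's area in this zone in
    conflict with this crop class".  Zero-denominator groups emit no row.
    """
    nvc.check_aligned(cdl, "crop grid")
    nvc.check_aligned(zones, "zone grid")
    state_by_zone = state_by_zone or {}
    if cdl_names is None:
        cdl_names = cdl_name_registry()

    ag, matched = relation_grids(nvc, cdl, table)
    mismatched = ag & ~matched
    grouping = table.variant_grouping()

    rows = []
    for zone in _zone_values(zones):
        in_zone = zones.values == zone
        for group in table.groups:
            in_group = in_zone & np.isin(nvc.values, list(group.nvc_values))
            denom = int(in_group.sum())
            if denom == 0:
                continue
            bad = in_group & mismatched
            if not bad.any():
                continue
            codes, counts = np.unique(cdl.values[bad], return_counts=True)
            for code, count in zip(codes, counts):
                name = cdl_names.get(int(code), f"CDL_{int(code)}")
                rows.append(
                    {
                        "FIPS": int(zone),
                        "State": state_by_zone.get(int(zone), ""),
                        "CDL_Year": int(year),
                        "CDL_Class": int(code),
                        "CDL_Name": name,
                        "NVC_Name": group.group_name,
                        "NCells_Mismatch": int(count),
                        "NCells_NVCClass_perCounty": denom,
                        "NVC_CDL_Pair": f"{group.group_name} - {name}",
                        "Pct_Mismatch": 100.0 * count / denom,
                    }
                )
    return pd.DataFrame(rows, columns=MISMATCH_COLUMNS)


def unresolved_stats(
    result: MergeResult,
    zones: CategoricalGrid,
    year: int = 0,
    state_by_zone: Mapping[int, str] | None = None,
    county_by_zone: Mapping[int, str] | None = None,
    region_by_zone: Mapping[int, str] | None = None,
    unresolved_name: str = UNRESOLVED_NAME,
    unresolved_code: int = -1001,
) -> pd.DataFrame:
    """Unresolved-pixel accounting per zone in the final merged raster.

    One row per zone; ``Pct_Unresolved`` uses the zone's *total* pixel count
    as denominator ("percent of county area").  Zones with no unresolved
    pixels get a zero row, so coverage of the zone list is complete.
    """
    result.merged.check_aligned(zones, "zone grid")
    state_by_zone = state_by_zone or {}
    county_by_zone = county_by_zone or {}
    region_by_zone = region_by_zone or {}

    rows = []
    for zone in _zone_values(zones):
        in_zone = zones.values == zone
        n_total = int(in_zone.sum())
        n_unres = int((in_zone & result.unresolved_mask).sum())
        rows.append(
            {
                "FIPS": int(zone),
                "State": state_by_zone.get(int(zone), ""),
                "CDL_Year": int(year),
                "County": county_by_zone.get(int(zone), ""),
                "LF2010_Region": region_by_zone.get(int(zone), ""),
                "MergedRaster_Class": unresolved_code,
                "MergedRaster_ClassName": unresolved_name,
                "NCells": n_unres,
                "Pct_Unresolved": 100.0 * n_unres / n_total if n_total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=UNRESOLVED_COLUMNS)


def weighted_accuracy(
    class_areas: Mapping[int, float],
    records: Iterable[AccuracyRecord],
) -> dict[str, float | None]:
    """Area-weighted mean accuracy over classes that have reference data.

    Weights are class areas (pixel counts).  Classes without reference data
    (or with reference flagged but accuracies absent) are excluded from the
    means and from the with-reference area.  Returns ``WtdUserAcc``,
    ``WtdProdAcc`` (None when no class contributes) and ``WithData_Pct`` =
    100 × (area of classes with reference data) / (total focal area).
    """
    if not class_areas:
        raise ValueError("class_areas must contain at least one class")
    for cls, area in class_areas.items():
        if area < 0:
            raise ValueError(f"negative area for class {cls}")
    by_class = {r.class_value: r for r in records}

    total = float(sum(class_areas.values()))
    user_num = prod_num = user_wt = prod_wt = with_data = 0.0
    for cls, area in class_areas.items():
        rec = by_class.get(cls)
        if rec is None or not rec.has_reference:
            continue
        if rec.users_acc is None and rec.producers_acc is None:
            continue  # reference flagged but no usable accuracy: treat as uncovered
        with_data += area
        if rec.users_acc is not None:
            user_num += area * rec.users_acc
            user_wt += area
        if rec.producers_acc is not None:
            prod_num += area * rec.producers_acc
            prod_wt += area

    return {
        "WtdUserAcc": user_num / user_wt if user_wt else None,
        "WtdProdAcc": prod_num / prod_wt if prod_wt else None,
        "WithData_Pct": 100.0 * with_data / total if total else 0.0,
    }


def span_accuracy(
    merged: CategoricalGrid,
    zones: CategoricalGrid,
    cdl_records: Iterable[AccuracyRecord],
    nvc_records: Iterable[AccuracyRecord],
    scheme: MergedCodeScheme | None = None,
    year: int = 0,
    dataset_name: str = "SPAN",
    focal_group: str = "Agricultural and natural classes",
    state_by_zone: Mapping[int, str] | None = None,
    county_by_zone: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-zone weighted accuracy of the merged raster.

    Negative-coded pixels are crops and draw accuracy from the crop-layer
    records (keyed by the decoded positive code); non-negative pixels draw
    from the vegetation-layer records.  Unresolved pixels are excluded from
    the focal area entirely.  Accuracy columns are NaN where no class in the
    zone has reference data.
    """
    merged.check_aligned(zones, "zone grid")
    scheme = scheme or MergedCodeScheme()
    state_by_zone = state_by_zone or {}
    county_by_zone = county_by_zone or {}
    cdl_by_class = {r.class_value: r for r in cdl_records}
    nvc_by_class = {r.class_value: r for r in nvc_records}

    rows = []
    for zone in _zone_values(zones):
        in_zone = zones.values == zone
        n_county = int(in_zone.sum())
        vals = merged.values[in_zone]
        vals = vals[vals != scheme.unresolved_code]
        vals = vals[vals != merged.nodata]
        n_focal = vals.size

        if n_focal:
            codes, areas = np.unique(vals, return_counts=True)
            class_areas: dict[int, int] = {}
            records: list[AccuracyRecord] = []
            for code, area in zip(codes, areas):
                code = int(code)
                if scheme.is_crop(code):
                    src, key = cdl_by_class, scheme.decode_crop(code)
                else:
                    src, key = nvc_by_class, code
                class_areas[code] = int(area)
                rec = src.get(key)
                if rec is not None:
                    records.append(
                        AccuracyRecord(code, rec.users_acc, rec.producers_acc,
                                       rec.has_reference)
                    )
                # absent record: treated as no-reference
            acc = weighted_accuracy(class_areas, records)
        else:
            acc = {"WtdUserAcc": None, "WtdProdAcc": None, "WithData_Pct": 0.0}

        rows.append(
            {
                "FIPS": int(zone),
                "State": state_by_zone.get(int(zone), ""),
                "CDL_Year": int(year),
                "County": county_by_zone.get(int(zone), ""),
                "FocalGroup": focal_group,
                "Dataset_Name": dataset_name,
                "NCells_County": n_county,
                "NCells_FocalGroup": int(n_focal),
                "FocalGroup_PctCounty": 100.0 * n_focal / n_county if n_county else 0.0,
                "WithData_PctFocalGroup": acc["WithData_Pct"],
                "WtdProdAcc": acc["WtdProdAcc"],
                "WtdUserAcc": acc["WtdUserAcc"],
            }
        )
    return pd.DataFrame(rows, columns=ACCURACY_COLUMNS)


def _fisher_dp(vals: np.ndarray, k: int) -> tuple[float, list[int]]:
    """Optimal contiguous k-partition of sorted *vals* by dynamic programming.

    Returns the minimal total within-class sum of squared deviations and the
    k−1 split positions (indices where a new class starts)."""
    n = vals.size
    # prefix sums for O(1) within-class SSD of vals[i:j]
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    csum2 = np.concatenate([[0.0], np.cumsum(vals**2)])

    def ssd(i: int, j: int) -> float:
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / (j - i)

    INF = float("inf")
    # cost[c][j]: best total SSD of splitting vals[:j] into c classes
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                cand = cost[c - 1][i] + ssd(i, j)
                if cand < best - 1e-12:  # first (leftmost) split wins ties
                    best, arg = cand, i
            cost[c][j] = best
            split[c][j] = arg

    splits = []
    j = n
    for c in range(k, 1, -1):
        j = split[c][j]
        splits.append(j)
    return float(cost[k][n]), splits[::-1]


def _check_jenks_args(values: Sequence[float], k: int) -> np.ndarray:
    vals = np.sort(np.asarray(values, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(vals).size
    if n_distinct < k:
        raise ValueError(f"need at least k={k} distinct values, got {n_distinct}")
    return vals


def jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Exact Jenks natural breaks (Fisher's optimal 1-D classification).

    Partitions the values into ``k`` contiguous classes minimizing the total
    within-class sum of squared deviations, by dynamic programming over the
    sorted values — exact, not the heuristic reseating variant.  Returns
    ``k + 1`` class edges ``[min, b1, …, b_{k-1}, max]``; class *i* spans
    ``(edges[i], edges[i+1]]`` (first class closed on the left).

    Requires at least ``k`` distinct values.
    """
    vals = _check_jenks_args(values, k)
    _, splits = _fisher_dp(vals, k)
    return [float(vals[0])] + [float(vals[i - 1]) for i in splits] + [float(vals[-1])]


def jenks_objective(values: Sequence[float], k: int) -> float:
    """Minimal total within-class SSD achieved by the optimal k-class
    partition (the quantity :func:`jenks_breaks` minimizes)."""
    vals = _check_jenks_args(values, k)
    return _fisher_dp(vals, k)[0]


def jenks_assign(values: Sequence[float], edges: Sequence[float]) -> np.ndarray:
    """Class index (0-based) of each value under Jenks edges."""
    vals = np.asarray(values, dtype=float)
    idx = np.searchsorted(np.asarray(edges[1:-1], dtype=float), vals, side="left")
    return idx


@dataclass
class VerificationReport:
    """Outcome of the automated output checks."""

    passed: bool
    unexpected_values: list[int] = field(default_factory=list)
    extent_ok: bool = True
    crs_ok: bool = True
    messages: list[str] = field(default_factory=list)


def verify_output(
    merged: CategoricalGrid,
    attribute_table: Sequence[AttributeRow],
    expected_extent: tuple[float, float, float, float] | None = None,
    expected_crs: str | None = None,
) -> VerificationReport:
    """Check a merged raster: every pixel value listed in the attribute table
    (nodata allowed), extent and CRS as expected.  Report-based; never raises
    for failed checks."""
    allowed = {row.Value for row in attribute_table} | {merged.nodata}
    present = np.unique(merged.values)
    unexpected = sorted(int(v) for v in present if int(v) not in allowed)

    report = VerificationReport(passed=True, unexpected_values=unexpected)
    if unexpected:
        report.passed = False
        report.messages.append(f"pixel values not in attribute table: {unexpected}")
    if expected_extent is not None and not np.allclose(merged.extent, expected_extent):
        report.extent_ok = False
        report.passed = False
        report.messages.append(
            f"extent {merged.extent} != expected {tuple(expected_extent)}"
        )
    if expected_crs is not None and merged.crs != expected_crs:
        report.crs_ok = False
        report.passed = False
        report.messages.append(f"CRS {merged.crs!r} != expected {expected_crs!r}")
    return report
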