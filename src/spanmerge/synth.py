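"""Synthetic aligned raster pairs with planted, exactly-known conflicts.

The generator emulates the structures the merge workflow has to cope with on
real vegetation/crop raster pairs, without requiring any download:

* a tessellation of axis-aligned rectangular *fields*, each wholly one
  vegetation class — agricultural fields carry a vegetation group variant
  code, natural fields a natural-vegetation code;
* annual crop layers where each agricultural field grows a crop drawn from
  its group's match set, optionally rotating between years (rotation inside
  the match set must produce zero conflicts);
* *scattered conflicts*: a known fraction of agricultural pixels whose crop
  value is flipped to a conflicting class — either a non-agricultural code or
  an agricultural code outside the focal group's match set (the two conflict
  kinds seen in practice);
* *noise pixels*: additional isolated single-pixel disagreements within
  otherwise clean fields;
* *whole-field conflicts*: entire fields whose crop layer disagrees
  everywhere, whose interiors are unresolvable under the matched-donor
  policy;
* a county-like zone map for the zonal statistics.

Every planted quantity is recorded as ground truth per zone and year.  The
unresolvability of each conflict pixel is recomputed here by a direct
per-pixel window scan — an implementation independent of the merge engine's
vectorised filter — so recovery tests compare two separate derivations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import CategoricalGrid
from .stats import AccuracyRecord
from .taxonomy import AttributeRow, ClassMatchTable, default_match_table

__all__ = [
    "FixtureSpec",
    "FixturePair",
    "ZoneYearTruth",
    "generate_pair",
    "generate_accuracy_records",
    "attribute_rows_for",
    "NATURAL_NVC_POOL",
    "NATURAL_CDL_POOL",
]

# synthetic natural-vegetation codes (outside any agricultural group) and the
# non-agricultural crop-layer codes used as conflicting covers
NATURAL_NVC_POOL = (6001, 6002, 6003, 6004, 6005, 6006)
NATURAL_CDL_POOL = (141, 142, 152, 195)
DEVELOPED_NVC_POOL = (7296, 7297, 7298, 7299)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic landscape.

    Defaults give a 128×128 grid of 10×10-pixel fields, ~60% agricultural,
    four zones, a scattered conflict rate of 4% plus 1.5% noise pixels
    (≈5.5% of agricultural pixels in conflict overall, the disagreement level
    typical of the real products), and one wholly conflicting field.
    """

    rows: int = 128
    cols: int = 128
    cell_size: float = 30.0
    crs: str = "EPSG:5070"
    n_zones: int = 4
    field_size: int = 10
    ag_fraction: float = 0.6
    years: tuple[int, ...] = (2016,)
    rotate: bool = True
    conflict_rate: float = 0.04
    noise_rate: float = 0.015
    whole_field_conflict_count: int = 1
    include_developed: bool = True
    natural_pool: tuple[int, ...] = NATURAL_NVC_POOL
    natural_cdl_pool: tuple[int, ...] = NATURAL_CDL_POOL
    radius: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ag_fraction", "conflict_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rows < 1 or self.cols < 1 or self.field_size < 1:
            raise ValueError("rows, cols and field_size must be positive")
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")
        if not self.years:
            raise ValueError("at least one year required")
        if not self.natural_pool or not self.natural_cdl_pool:
            raise ValueError("code pools must be nonempty")


@dataclass
class ZoneYearTruth:
    """Planted counts for one zone and crop-layer year."""

    zone: int
    year: int
    zone_pixels: int
    ag_pixels: int
    mismatch_total: int
    unresolved_total: int
    mismatch_by_pair: dict[tuple[str, int], int]   # (group name, crop code) -> count
    group_pixels: dict[str, int]                   # group name -> pixels in zone


@dataclass
class FixturePair:
    """Generated landscape: grids plus exact planted truth."""

    nvc: CategoricalGrid
    cdl_by_year: dict[int, CategoricalGrid]
    zones: CategoricalGrid
    truth: dict[tuple[int, int], ZoneYearTruth]    # (zone, year) -> truth

    def truth_for(self, zone: int, year: int) -> ZoneYearTruth:
        return self.truth[(zone, year)]


def _field_blocks(rows: int, cols: int, size: int) -> list[tuple[slice, slice]]:
    return [
        (slice(r, min(r + size, rows)), slice(c, min(c + size, cols)))
        for r in range(0, rows, size)
        for c in range(0, cols, size)
    ]


def _zone_grid(spec: FixtureSpec) -> np.ndarray:
    # FIPS-like codes over horizontal bands of roughly equal height
    zones = np.empty((spec.rows, spec.cols), dtype=np.int32)
    edges = np.linspace(0, spec.rows, spec.n_zones + 1).astype(int)
    for i in range(spec.n_zones):
        zones[edges[i]:edges[i + 1], :] = 1001 + 2 * i
    return zones


def _unresolvable_mask(
    mismatched: np.ndarray, matched: np.ndarray, radius: int
) -> np.ndarray:
    """Direct per-pixel window scan: a conflict pixel is unresolvable iff no
    matched pixel lies within Chebyshev distance <= radius.  Deliberately a
    separate derivation from the merge engine's filter-based counting."""
    rows, cols = mismatched.shape
    pad = np.zeros((rows + 2 * radius, cols + 2 * radius), dtype=bool)
    pad[radius:radius + rows, radius:radius + cols] = matched
    out = np.zeros_like(mismatched)
    for r, c in zip(*np.nonzero(mismatched)):
        window = pad[r:r + 2 * radius + 1, c:c + 2 * radius + 1]
        out[r, c] = not window.any()
    return out


def generate_pair(
    spec: FixtureSpec, table: ClassMatchTable | None = None
) -> FixturePair:
    """Generate an aligned vegetation/crop grid pair, zone map and truth.

    Deterministic for a fixed spec (the seed is part of the spec): the same
    spec always yields bit-identical grids.
    """
    table = table or default_match_table()
    rng = np.random.default_rng(spec.seed)
    groups = list(table.groups)
    cdl_ag = sorted(table.cdl_ag_set)

    blocks = _field_blocks(spec.rows, spec.cols, spec.field_size)
    nvc = np.empty((spec.rows, spec.cols), dtype=np.int32)
    base_crop = {}            # block index -> dict year -> crop code
    group_of_block: dict[int, object] = {}

    ag_blocks: list[int] = []
    for bi, (rs, cs) in enumerate(blocks):
        if rng.random() < spec.ag_fraction:
            group = groups[rng.integers(len(groups))]
            variant = sorted(group.nvc_values)[rng.integers(len(group.nvc_values))]
            nvc[rs, cs] = variant
            group_of_block[bi] = group
            ag_blocks.append(bi)
            match_set = sorted(group.cdl_values)
            crops = {}
            for year in spec.years:
                if spec.rotate or not crops:
                    crops[year] = match_set[rng.integers(len(match_set))]
                else:
                    crops[year] = next(iter(crops.values()))
            base_crop[bi] = crops
        else:
            pool = list(spec.natural_pool)
            if spec.include_developed and rng.random() < 0.1:
                pool = list(DEVELOPED_NVC_POOL)
            nvc[rs, cs] = pool[rng.integers(len(pool))]

    if spec.whole_field_conflict_count > len(ag_blocks):
        raise ValueError(
            f"requested {spec.whole_field_conflict_count} whole-field conflicts "
            f"but only {len(ag_blocks)} agricultural fields were generated"
        )
    conflict_blocks = set(
        rng.choice(ag_blocks, size=spec.whole_field_conflict_count, replace=False)
        .tolist()
        if spec.whole_field_conflict_count
        else []
    )

    zones_arr = _zone_grid(spec)
    ag_mask = np.isin(nvc, list(table.nvc_ag_set))

    cdl_by_year: dict[int, CategoricalGrid] = {}
    truth: dict[tuple[int, int], ZoneYearTruth] = {}
    meta = dict(cell_size=spec.cell_size, crs=spec.crs)
    zone_codes = np.unique(zones_arr)

    grouping = table.variant_grouping()
    group_pixels_by_zone: dict[tuple[int, str], int] = {}
    for z in zone_codes:
        in_zone = zones_arr == z
        for g in groups:
            n = int((in_zone & np.isin(nvc, list(g.nvc_values))).sum())
            if n:
                group_pixels_by_zone[(int(z), g.group_name)] = n

    for year in spec.years:
        cdl = np.empty((spec.rows, spec.cols), dtype=np.int32)
        year_rng = np.random.default_rng([spec.seed, year])
        for bi, (rs, cs) in enumerate(blocks):
            if bi in group_of_block:
                cdl[rs, cs] = base_crop[bi][year]
            else:
                cdl[rs, cs] = spec.natural_cdl_pool[
                    year_rng.integers(len(spec.natural_cdl_pool))
                ]

        # whole-field conflicts: the crop layer calls the entire field a
        # non-agricultural cover
        for bi in conflict_blocks:
            rs, cs = blocks[bi]
            cdl[rs, cs] = spec.natural_cdl_pool[0]

        # scattered conflicts + isolated noise pixels on the remaining ag area
        clean_ag = ag_mask.copy()
        for bi in conflict_blocks:
            rs, cs = blocks[bi]
            clean_ag[rs, cs] = False
        coords = np.argwhere(clean_ag)
        n_conflict = int(round(spec.conflict_rate * len(coords)))
        n_noise = int(round(spec.noise_rate * len(coords)))
        picked = year_rng.choice(len(coords), size=min(n_conflict + n_noise, len(coords)),
                                 replace=False)
        for j, idx in enumerate(picked):
            r, c = coords[idx]
            group = table.group_of(int(nvc[r, c]))
            if j < n_conflict and year_rng.random() < 0.5:
                # conflict kind (a): non-agricultural cover
                cdl[r, c] = spec.natural_cdl_pool[
                    year_rng.integers(len(spec.natural_cdl_pool))
                ]
            else:
                # conflict kind (b): agricultural code outside the match set
                outside = [c_ for c_ in cdl_ag if c_ not in group.cdl_values]
                if not outside:
                    raise ValueError(
                        f"no conflicting agricultural code exists for group "
                        f"{group.group_name!r}"
                    )
                cdl[r, c] = outside[year_rng.integers(len(outside))]

        cdl_by_year[year] = CategoricalGrid(values=cdl, **meta)

        # ground truth by direct per-pixel classification
        matched = np.zeros_like(ag_mask)
        mism = np.zeros_like(ag_mask)
        for g in groups:
            in_g = np.isin(nvc, list(g.nvc_values))
            matched |= in_g & np.isin(cdl, list(g.cdl_values))
        mism = ag_mask & ~matched
        unres = _unresolvable_mask(mism, matched, spec.radius)

        for z in zone_codes:
            in_zone = zones_arr == z
            by_pair: dict[tuple[str, int], int] = {}
            for r, c in zip(*np.nonzero(mism & in_zone)):
                key = (grouping[int(nvc[r, c])], int(cdl[r, c]))
                by_pair[key] = by_pair.get(key, 0) + 1
            truth[(int(z), year)] = ZoneYearTruth(
                zone=int(z),
                year=year,
                zone_pixels=int(in_zone.sum()),
                ag_pixels=int((ag_mask & in_zone).sum()),
                mismatch_total=int((mism & in_zone).sum()),
                unresolved_total=int((unres & in_zone).sum()),
                mismatch_by_pair=by_pair,
                group_pixels={
                    g.group_name: group_pixels_by_zone[(int(z), g.group_name)]
                    for g in groups
                    if (int(z), g.group_name) in group_pixels_by_zone
                },
            )

    return FixturePair(
        nvc=CategoricalGrid(values=nvc, **meta),
        cdl_by_year=cdl_by_year,
        zones=CategoricalGrid(values=zones_arr, **meta),
        truth=truth,
    )


def generate_accuracy_records(
    classes: Sequence[int],
    seed: int = 0,
    acc_range: tuple[float, float] = (40.0, 95.0),
    frac_without_reference: float = 0.0,
) -> list[AccuracyRecord]:
    """Reproducible per-class accuracy records; a stated fraction of classes
    lacks reference data entirely (no accuracy values)."""
    if not classes:
        raise ValueError("classes must be nonempty")
    rng = np.random.default_rng(seed)
    n_missing = int(round(frac_without_reference * len(classes)))
    missing = set(
        rng.choice(len(classes), size=n_missing, replace=False).tolist()
        if n_missing
        else []
    )
    records = []
    lo, hi = acc_range
    for i, cls in enumerate(classes):
        if i in missing:
            records.append(AccuracyRecord(class_value=int(cls), has_reference=False))
        else:
            records.append(
                AccuracyRecord(
                    class_value=int(cls),
                    users_acc=float(np.round(rng.uniform(lo, hi), 1)),
                    producers_acc=float(np.round(rng.uniform(lo, hi), 1)),
                )
            )
    return records


def attribute_rows_for(
    codes: Sequence[int], names: dict[int, str] | None = None, seed: int = 0
) -> list[AttributeRow]:
    """Attribute rows with reproducible colors for the given codes (synthetic
    stand-in for a published color map)."""
    rng = np.random.default_rng(seed)
    names = names or {}
    rows = []
    for code in sorted(set(int(c) for c in codes)):
        r, g, b = (int(x) for x in rng.integers(0, 256, size=3))
        rows.append(
            AttributeRow(Value=code, Class_Name=names.get(code, f"Class {code}"),
                         Red=r, Green=g, Blue=b)
        )
    return rows
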