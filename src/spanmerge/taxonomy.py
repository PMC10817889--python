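"""Class-match semantics between vegetation-map and crop-map legends.

The vegetation layer (NVC-style) maps agriculture as ~10 broad groups, each
appearing as several geographic/climatic variant codes (e.g. Vineyard as 7961,
7971, 7981, 7991).  The crop layer (CDL-style) maps agriculture as specific
crop codes.  A :class:`ClassMatchTable` records, per vegetation group, the set
of crop codes considered consistent with it — synonyms, subsets, or rotation
partners.  Six broad groups (row crop, close-grown crop, fallow/idle, pasture
and hayland, wheat, and their combination) share one pooled crop set because
any of ~90 annual/rotational crops can legitimately occupy them in a given
year.

The merged raster uses a single integer code space: vegetation codes pass
through unchanged, crop codes are negated so they cannot collide with
vegetation codes, and the sentinel −1001 marks agricultural conflicts that
could not be resolved (:class:`MergedCodeScheme`).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Relation",
    "MatchGroup",
    "ClassMatchTable",
    "MergedCodeScheme",
    "AttributeRow",
    "MatchTableError",
    "load_match_table",
    "default_match_table",
    "cdl_code_registry",
    "cdl_name_registry",
    "classify_pair",
    "build_attribute_table",
    "UNRESOLVED_CODE",
    "UNRESOLVED_NAME",
]

UNRESOLVED_CODE = -1001
UNRESOLVED_NAME = "Unresolved land cover"


class MatchTableError(ValueError):
    """Malformed or inconsistent class-match table."""


class Relation(enum.Enum):
    """Relation of one (vegetation value, crop value) pixel pair."""

    PASSTHROUGH = "passthrough"  # vegetation value is not agricultural
    MATCHED = "matched"          # crop value lies in the group's match set
    MISMATCHED = "mismatched"    # agricultural vegetation over a conflicting crop value


@dataclass(frozen=True)
class MatchGroup:
    """One vegetation agricultural group and its matching crop codes."""

    group_name: str
    nvc_values: frozenset[int]
    cdl_values: frozenset[int]
    cdl_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.nvc_values or not self.cdl_values:
            raise MatchTableError(f"group {self.group_name!r}: empty code set")
        for code in list(self.nvc_values) + list(self.cdl_values):
            if code <= 0:
                raise MatchTableError(
                    f"group {self.group_name!r}: non-positive code {code}"
                )


class ClassMatchTable:
    """Lookup from vegetation agricultural codes to their crop match sets.

    ``nvc_ag_set`` / ``cdl_ag_set`` are the unions over all groups; ``lookup``
    maps every vegetation agricultural code to its (unique) group.  A crop code
    may legally appear in several groups (Avocados is both an orchard crop and
    a rotation crop), so no global uniqueness is imposed on crop codes.
    """

    def __init__(self, groups: Sequence[MatchGroup]):
        if not groups:
            raise MatchTableError("match table has no groups")
        self.groups: tuple[MatchGroup, ...] = tuple(groups)
        self.lookup: dict[int, MatchGroup] = {}
        for g in self.groups:
            for v in g.nvc_values:
                if v in self.lookup:
                    raise MatchTableError(
                        f"NVC code {v} appears in groups "
                        f"{self.lookup[v].group_name!r} and {g.group_name!r}"
                    )
                self.lookup[v] = g
        self.nvc_ag_set: frozenset[int] = frozenset(self.lookup)
        self.cdl_ag_set: frozenset[int] = frozenset(
            c for g in self.groups for c in g.cdl_values
        )

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, nvc_value: int) -> MatchGroup:
        try:
            return self.lookup[nvc_value]
        except KeyError:
            raise KeyError(f"NVC code {nvc_value} is not agricultural") from None

    def group_by_name(self, name: str) -> MatchGroup:
        for g in self.groups:
            if g.group_name == name:
                return g
        raise KeyError(name)

    def variant_grouping(self) -> dict[int, str]:
        """Map each vegetation agricultural code to its group name — pools the
        geographic (Western/Eastern) and climatic (Cool/Warm) variants."""
        return {v: g.group_name for v, g in self.lookup.items()}

    def classify(self, nvc: int, cdl: int) -> Relation:
        group = self.lookup.get(nvc)
        if group is None:
            return Relation.PASSTHROUGH
        return Relation.MATCHED if cdl in group.cdl_values else Relation.MISMATCHED


def classify_pair(nvc: int, cdl: int, table: ClassMatchTable) -> Relation:
    """Classify one (vegetation value, crop value) pixel pair.

    PASSTHROUGH if the vegetation value is not agricultural; MATCHED if the
    crop value is in the match set of the vegetation group; MISMATCHED
    otherwise — including crop-layer nodata/background and non-agricultural
    crop-layer classes, which count as conflicts, not errors.  Total over all
    integer pairs.
    """
    return table.classify(nvc, cdl)


def _parse_int_list(cell: str, row_label: str) -> list[int]:
    items = [s.strip() for s in cell.split(";") if s.strip()]
    try:
        return [int(s) for s in items]
    except ValueError as exc:
        raise MatchTableError(f"{row_label}: bad integer list {cell!r}") from exc


def load_match_table(path: str | Path, strict: bool = True) -> ClassMatchTable:
    """Load a class-match table from CSV.

    Expected columns: ``group_name``, ``nvc_values``, ``cdl_names``,
    ``cdl_values``; list-valued cells are semicolon-delimited.  With
    ``strict`` on (default), duplicate vegetation codes across groups and
    non-positive codes are rejected.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"group_name", "nvc_values", "cdl_names", "cdl_values"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MatchTableError(
                f"{path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        groups = []
        for i, row in enumerate(reader, start=2):
            label = f"{path.name} row {i}"
            if any(row.get(k) in (None, "") for k in required):
                raise MatchTableError(f"{label}: missing field")
            nvc_values = _parse_int_list(row["nvc_values"], label)
            cdl_values = _parse_int_list(row["cdl_values"], label)
            cdl_names = tuple(
                s.strip() for s in row["cdl_names"].split(";") if s.strip()
            )
            if len(cdl_names) != len(cdl_values):
                raise MatchTableError(
                    f"{label}: {len(cdl_names)} names vs {len(cdl_values)} codes"
                )
            if not strict:
                nvc_values = [v for v in nvc_values if v > 0] or nvc_values
            groups.append(
                MatchGroup(
                    group_name=row["group_name"].strip(),
                    nvc_values=frozenset(nvc_values),
                    cdl_values=frozenset(cdl_values),
                    cdl_names=cdl_names,
                )
            )
    if not groups:
        raise MatchTableError(f"{path}: no data rows")
    return ClassMatchTable(groups)


def _data_path(name: str) -> Path:
    return Path(resources.files("spanmerge").joinpath("data", name))  # type: ignore[arg-type]


def default_match_table() -> ClassMatchTable:
    """The packaged default table: 10 vegetation agricultural groups, the last
    six sharing the pooled ~90-crop rotation match set."""
    return load_match_table(_data_path("match_table.csv"))


def cdl_code_registry() -> dict[str, int]:
    """Packaged crop-layer legend: class name → integer code."""
    with open(_data_path("cdl_codes.csv"), newline="") as fh:
        return {row["name"]: int(row["code"]) for row in csv.DictReader(fh)}


def cdl_name_registry() -> dict[int, str]:
    """Packaged crop-layer legend: integer code → class name."""
    return {code: name for name, code in cdl_code_registry().items()}


@dataclass(frozen=True)
class MergedCodeScheme:
    """Output code conventions of the merged raster.

    Crop codes are written as their negatives; vegetation codes (natural,
    developed, nodata) pass through; ``unresolved_code`` marks agricultural
    conflicts with no eligible donor within the search window.
    """

    unresolved_code: int = UNRESOLVED_CODE

    def encode_crop(self, cdl_value: int) -> int:
        return -cdl_value

    def decode_crop(self, merged_value: int) -> int:
        if merged_value >= 0 or merged_value == self.unresolved_code:
            raise ValueError(f"{merged_value} is not an encoded crop code")
        return -merged_value

    def is_crop(self, merged_value: int) -> bool:
        return merged_value < 0 and merged_value != self.unresolved_code

    def validate(self, table: ClassMatchTable) -> None:
        negated = {-c for c in table.cdl_ag_set}
        if self.unresolved_code in negated:
            raise MatchTableError(
                f"unresolved code {self.unresolved_code} collides with a negated crop code"
            )
        if self.unresolved_code in table.nvc_ag_set:
            raise MatchTableError(
                f"unresolved code {self.unresolved_code} collides with an NVC code"
            )


@dataclass(frozen=True)
class AttributeRow:
    """One row of a raster attribute table: code, class name, RGB color."""

    Value: int
    Class_Name: str
    Red: int = 0
    Green: int = 0
    Blue: int = 0

    def __post_init__(self) -> None:
        for c in (self.Red, self.Green, self.Blue):
            if not 0 <= c <= 255:
                raise ValueError(f"color component {c} outside [0, 255]")


def build_attribute_table(
    table: ClassMatchTable,
    nvc_attributes: Sequence[AttributeRow],
    cdl_attributes: Sequence[AttributeRow],
    scheme: MergedCodeScheme | None = None,
    nvc_codes_in_use: Iterable[int] | None = None,
) -> list[AttributeRow]:
    """Merged-raster attribute table.

    Vegetation rows are kept unchanged; crop rows whose code is agricultural
    are re-emitted with the negated code; one row is added for the unresolved
    sentinel.  When ``nvc_codes_in_use`` is given, every such code must have a
    source row (a completeness error lists any that do not).
    """
    scheme = scheme or MergedCodeScheme()
    scheme.validate(table)

    merged: list[AttributeRow] = list(nvc_attributes)
    have_nvc = {r.Value for r in nvc_attributes}
    missing: list[int] = []
    if nvc_codes_in_use is not None:
        missing.extend(sorted(set(nvc_codes_in_use) - have_nvc))

    have_cdl = {r.Value for r in cdl_attributes}
    missing.extend(sorted(table.cdl_ag_set - have_cdl))
    if missing:
        raise MatchTableError(f"no attribute row for codes: {missing}")

    for row in cdl_attributes:
        if row.Value in table.cdl_ag_set:
            merged.append(
                AttributeRow(
                    Value=scheme.encode_crop(row.Value),
                    Class_Name=row.Class_Name,
                    Red=row.Red,
                    Green=row.Green,
                    Blue=row.Blue,
                )
            )
    merged.append(
        AttributeRow(Value=scheme.unresolved_code, Class_Name=UNRESOLVED_NAME,
                     Red=255, Green=0, Blue=255)
    )
    values = [r.Value for r in merged]
    if len(values) != len(set(values)):
        dupes = sorted({v for v in values if values.count(v) > 1})
        raise MatchTableError(f"duplicate attribute values: {dupes}")
    return merged


def validate_registry_against_table(table: ClassMatchTable | None = None) -> None:
    """Cross-check the packaged name→code registry against the codes printed
    in the match table itself (fallow/pasture/hay 61/176/37, grapes 69,
    berries 242/250, aquaculture 92/111 and the orchard codes)."""
    table = table or default_match_table()
    registry = cdl_code_registry()
    for group in table.groups:
        for name in group.cdl_names:
            if name not in registry:
                raise MatchTableError(f"CDL name {name!r} missing from registry")
            if registry[name] not in group.cdl_values:
                raise MatchTableError(
                    f"registry code {registry[name]} for {name!r} not in "
                    f"group {group.group_name!r}"
                )
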