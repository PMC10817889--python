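"""File I/O: GeoTIFF rasters, attribute/match-table CSVs, statistics CSVs,
and plain-text merge configs.

GeoTIFF support is a small self-contained layer over ``tifffile`` that reads
and writes the standard GeoTIFF tags this workflow needs — pixel scale
(33550), tiepoint (33922), the GeoKey directory (34735, carrying the EPSG
code) and GDAL-style nodata (42113) — giving lossless round-trips of values,
geotransform, CRS and nodata for single-band categorical rasters.  Values are
written as 32-bit signed integers so negated crop codes and the −1001
sentinel are always representable.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .grid import CategoricalGrid
from .merge import MergeConfig
from .stats import ACCURACY_COLUMNS, MISMATCH_COLUMNS, UNRESOLVED_COLUMNS, AccuracyRecord
from .taxonomy import AttributeRow

__all__ = [
    "RasterIOError",
    "read_raster",
    "write_raster",
    "read_attribute_table",
    "write_attribute_table",
    "write_stats_csv",
    "read_accuracy_records",
    "write_accuracy_records",
    "read_config",
    "write_config",
    "STATS_SCHEMAS",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids: model type (1=projected, 2=geographic), projected CRS EPSG,
# geographic CRS EPSG
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_CRS = 2048
_KEY_PROJECTED_CRS = 3072

STATS_SCHEMAS: dict[str, list[str]] = {
    "pixel_mismatch": MISMATCH_COLUMNS,
    "unresolved_conflict": UNRESOLVED_COLUMNS,
    "accuracy_datacoverage": ACCURACY_COLUMNS,
    "attribute_table": ["Value", "Class_Name", "Red", "Green", "Blue"],
}


class RasterIOError(IOError):
    """Unreadable raster or missing georeferencing."""


def _epsg_of(crs: str) -> int:
    try:
        auth, code = crs.split(":")
        if auth.upper() != "EPSG":
            raise ValueError
        return int(code)
    except ValueError:
        raise RasterIOError(
            f"CRS {crs!r} is not an EPSG code; only EPSG-coded CRSs are written"
        ) from None


def write_raster(
    grid: CategoricalGrid,
    path: str | Path,
    attribute_table: Sequence[AttributeRow] | None = None,
    compression: str | None = None,
) -> Path:
    """Write a grid as a single-band int32 GeoTIFF.

    When an attribute table is given, it is written alongside the raster as a
    sidecar CSV named ``<raster>.attributes.csv`` (TIFF palettes only exist
    for unsigned 8/16-bit data, which cannot hold this product's negative
    codes — the published attribute-CSV form is the color map of record).
    """
    path = Path(path)
    if attribute_table is not None:
        write_attribute_table(
            attribute_table, path.with_suffix(path.suffix + ".attributes.csv")
        )
    epsg = _epsg_of(grid.crs)
    model_type = 2 if 4000 <= epsg < 5000 else 1
    crs_key = _KEY_GEOGRAPHIC_CRS if model_type == 2 else _KEY_PROJECTED_CRS
    geokeys = (
        1, 1, 0, 2,
        _KEY_MODEL_TYPE, 0, 1, model_type,
        crs_key, 0, 1, epsg,
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(grid.x_origin), float(grid.y_origin), 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(
        path,
        grid.values.astype(np.int32),
        extratags=extratags,
        compression=compression,
    )
    return path


def read_raster(path: str | Path) -> CategoricalGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale, tiepoint and EPSG geokeys)."""
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = {
                code: page.tags[code].value
                for code in (_TAG_PIXEL_SCALE, _TAG_TIEPOINT, _TAG_GEOKEYS,
                             _TAG_GDAL_NODATA)
                if code in page.tags
            }
    except Exception as exc:  # malformed TIFF
        raise RasterIOError(f"cannot read raster {path}: {exc}") from exc

    if values.ndim != 2:
        raise RasterIOError(f"{path}: expected a single-band raster")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise RasterIOError(f"{path}: missing georeferencing tags")
    scale = tags[_TAG_PIXEL_SCALE]
    tie = tags[_TAG_TIEPOINT]
    if _TAG_GEOKEYS not in tags:
        raise RasterIOError(f"{path}: missing CRS (GeoKey directory)")
    keys = tags[_TAG_GEOKEYS]
    epsg = None
    for i in range(4, len(keys), 4):
        if keys[i] in (_KEY_PROJECTED_CRS, _KEY_GEOGRAPHIC_CRS):
            epsg = keys[i + 3]
    if not epsg:
        raise RasterIOError(f"{path}: no EPSG code in GeoKey directory")

    nodata = -9999
    if _TAG_GDAL_NODATA in tags:
        nodata = int(float(str(tags[_TAG_GDAL_NODATA])))

    return CategoricalGrid(
        values=values.astype(np.int32),
        x_origin=float(tie[3]) - float(tie[0]) * float(scale[0]),
        y_origin=float(tie[4]) + float(tie[1]) * float(scale[1]),
        cell_size=float(scale[0]),
        crs=f"EPSG:{epsg}",
        nodata=nodata,
    )


def write_attribute_table(rows: Sequence[AttributeRow], path: str | Path) -> Path:
    """Attribute CSV with the exact published header
    ``Value,Class_Name,Red,Green,Blue``."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(STATS_SCHEMAS["attribute_table"])
        for row in rows:
            w.writerow([row.Value, row.Class_Name, row.Red, row.Green, row.Blue])
    return path


def read_attribute_table(path: str | Path) -> list[AttributeRow]:
    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(
                AttributeRow(
                    Value=int(rec["Value"]),
                    Class_Name=rec["Class_Name"],
                    Red=int(rec["Red"]),
                    Green=int(rec["Green"]),
                    Blue=int(rec["Blue"]),
                )
            )
    return out


def write_stats_csv(
    records: pd.DataFrame, schema_name: str, path: str | Path
) -> Path:
    """Write one statistics product with its schema's exact column header.

    ``schema_name`` is one of ``pixel_mismatch``, ``unresolved_conflict``,
    ``accuracy_datacoverage``; the frame's columns must match the schema
    exactly (mixed or unknown schemas are rejected)."""
    if schema_name not in STATS_SCHEMAS:
        raise ValueError(
            f"unknown schema {schema_name!r}; expected one of {sorted(STATS_SCHEMAS)}"
        )
    columns = STATS_SCHEMAS[schema_name]
    if list(records.columns) != columns:
        raise ValueError(
            f"records do not follow schema {schema_name!r}: "
            f"columns {list(records.columns)} != {columns}"
        )
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def write_accuracy_records(records: Iterable[AccuracyRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class_value", "users_acc", "producers_acc", "has_reference"])
        for r in records:
            w.writerow(
                [
                    r.class_value,
                    "" if r.users_acc is None else r.users_acc,
                    "" if r.producers_acc is None else r.producers_acc,
                    int(r.has_reference),
                ]
            )
    return path


def read_accuracy_records(path: str | Path) -> list[AccuracyRecord]:
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(
                AccuracyRecord(
                    class_value=int(rec["class_value"]),
                    users_acc=float(rec["users_acc"]) if rec["users_acc"] else None,
                    producers_acc=(
                        float(rec["producers_acc"]) if rec["producers_acc"] else None
                    ),
                    has_reference=bool(int(rec["has_reference"])),
                )
            )
    return out


def read_config(path: str | Path) -> MergeConfig:
    """Plain-text ``key = value`` merge configuration (radius, donor_policy,
    tie_break, unresolved_code); unknown keys are rejected."""
    fields = {"radius": int, "donor_policy": str, "tie_break": str,
              "unresolved_code": int}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path} line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path} line {lineno}: unknown key {key!r}")
        kwargs[key] = fields[key](value)
    return MergeConfig(**kwargs)


def write_config(config: MergeConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        f"radius = {config.radius}\n"
        f"donor_policy = {config.donor_policy}\n"
        f"tie_break = {config.tie_break}\n"
        f"unresolved_code = {config.unresolved_code}\n"
    )
    return path
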