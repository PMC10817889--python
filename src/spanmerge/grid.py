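"""In-memory container for categorical land-cover rasters.

A :class:`CategoricalGrid` is a 2-D integer array plus the minimal spatial
metadata needed for this workflow: an affine north-up geotransform (origin and
square cell size), a CRS identifier, and a nodata code.  Grids are merged
pixel-by-pixel, so the only spatial operation the package ever performs on the
metadata is an exact-alignment check — no resampling or reprojection is done,
mirroring how co-registered 30 m national products are combined in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CategoricalGrid", "AlignmentError"]


class AlignmentError(ValueError):
    """Raised when two grids do not share shape, geotransform, and CRS."""


@dataclass
class CategoricalGrid:
    """2-D integer land-cover grid with geotransform, CRS id and nodata code.

    Parameters
    ----------
    values
        Integer array of shape ``(rows, cols)``.  Stored as a signed integer
        dtype so negative merged codes (negated crop codes, the unresolved
        sentinel) are representable.
    x_origin, y_origin
        Map coordinates of the outer corner of the upper-left pixel.
    cell_size
        Square pixel edge length in CRS units (30 m for the real products;
        arbitrary in synthetic fixtures).
    crs
        CRS identifier, e.g. ``"EPSG:5070"``.
    nodata
        Integer code marking pixels outside the data footprint.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 30.0
    crs: str = "EPSG:5070"
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError(f"grid values must be integers, got {self.values.dtype}")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def transform(self) -> tuple[float, float, float]:
        """(x_origin, y_origin, cell_size) — the north-up geotransform."""
        return (self.x_origin, self.y_origin, self.cell_size)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) bounding box in CRS units."""
        rows, cols = self.shape
        return (
            self.x_origin,
            self.y_origin - rows * self.cell_size,
            self.x_origin + cols * self.cell_size,
            self.y_origin,
        )

    def is_aligned(self, other: "CategoricalGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.transform, other.transform)
            and self.crs == other.crs
        )

    def check_aligned(self, other: "CategoricalGrid", label: str = "grid") -> None:
        """Raise :class:`AlignmentError` unless *other* shares this grid's
        shape, geotransform and CRS.  Never resamples."""
        if self.shape != other.shape:
            raise AlignmentError(
                f"{label}: shape {other.shape} does not match {self.shape}"
            )
        if not np.allclose(self.transform, other.transform):
            raise AlignmentError(
                f"{label}: geotransform {other.transform} does not match {self.transform}"
            )
        if self.crs != other.crs:
            raise AlignmentError(f"{label}: CRS {other.crs!r} does not match {self.crs!r}")

    def window(self, rows: slice, cols: slice) -> "CategoricalGrid":
        """Sub-grid view over half-open row/col ranges, with a shifted origin."""
        r0 = rows.start or 0
        c0 = cols.start or 0
        return replace(
            self,
            values=self.values[rows, cols],
            x_origin=self.x_origin + c0 * self.cell_size,
            y_origin=self.y_origin - r0 * self.cell_size,
        )

    def like(self, values: np.ndarray) -> "CategoricalGrid":
        """New grid with the same spatial metadata and different values."""
        return replace(self, values=values)
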