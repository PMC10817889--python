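"""Tiled execution of the merge over large extents.

Large rasters are split into square tiles of roughly a target area (default
1000 km²).  Each tile is processed on a *padded* window — the core window
expanded by ``overlap`` pixels (default 3, i.e. 90 m at 30 m cells) and
clipped to the grid — and only the core is written back.  Because the
conflict-resolution window has Chebyshev radius ``radius`` and donor
eligibility is a pure per-pixel function of the inputs, an overlap of at least
``radius`` pixels guarantees every core pixel sees its complete neighborhood,
making the tiled mosaic bit-identical to a monolithic run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CategoricalGrid
from .merge import MergeConfig, MergeResult, merge, relation_grids
from .taxonomy import ClassMatchTable, MergedCodeScheme

__all__ = ["Tile", "TilePlan", "plan_tiles", "merge_tiled"]

TARGET_TILE_AREA = 1000 * 1e6  # 1000 km² in m²


@dataclass(frozen=True)
class Tile:
    """One tile: half-open core row/col ranges and the padded ranges."""

    tile_id: int
    core_rows: tuple[int, int]
    core_cols: tuple[int, int]
    padded_rows: tuple[int, int]
    padded_cols: tuple[int, int]

    @property
    def core(self) -> tuple[slice, slice]:
        return slice(*self.core_rows), slice(*self.core_cols)

    @property
    def padded(self) -> tuple[slice, slice]:
        return slice(*self.padded_rows), slice(*self.padded_cols)

    @property
    def core_in_padded(self) -> tuple[slice, slice]:
        """Core window expressed in padded-window-local coordinates."""
        return (
            slice(self.core_rows[0] - self.padded_rows[0],
                  self.core_rows[1] - self.padded_rows[0]),
            slice(self.core_cols[0] - self.padded_cols[0],
                  self.core_cols[1] - self.padded_cols[0]),
        )


@dataclass(frozen=True)
class TilePlan:
    """Deterministic row-major tiling: core windows partition the grid;
    padded windows add ``overlap`` pixels on every side, clipped to the grid."""

    grid_shape: tuple[int, int]
    tile_side: int
    overlap: int
    tiles: tuple[Tile, ...]

    def to_frame(self) -> pd.DataFrame:
        """Serializable table (tile id + bounds) for logging or resume."""
        return pd.DataFrame(
            [
                {
                    "tile_id": t.tile_id,
                    "core_row_start": t.core_rows[0], "core_row_stop": t.core_rows[1],
                    "core_col_start": t.core_cols[0], "core_col_stop": t.core_cols[1],
                    "padded_row_start": t.padded_rows[0], "padded_row_stop": t.padded_rows[1],
                    "padded_col_start": t.padded_cols[0], "padded_col_stop": t.padded_cols[1],
                }
                for t in self.tiles
            ]
        )


def plan_tiles(
    grid_shape: tuple[int, int],
    cell_size: float = 30.0,
    target_area: float = TARGET_TILE_AREA,
    overlap: int = 3,
    radius: int | None = None,
    tile_side: int | None = None,
) -> TilePlan:
    """Plan a row-major tiling of ``grid_shape``.

    The tile side defaults to ``floor(sqrt(target_area) / cell_size)`` pixels
    (≈1054 at 30 m cells and 1000 km²) and may be given directly via
    ``tile_side``.  Tiles in the last row/column may be smaller.  ``overlap``
    must be at least the merge radius when one is given.
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    if radius is not None and overlap < radius:
        raise ValueError(
            f"tile overlap ({overlap} px) must be >= merge radius ({radius} px)"
        )
    if tile_side is None:
        tile_side = max(1, math.floor(math.sqrt(target_area) / cell_size))
    if tile_side < 1:
        raise ValueError("tile side must be >= 1 pixel")

    tiles: list[Tile] = []
    tid = 0
    for r0 in range(0, rows, tile_side):
        r1 = min(r0 + tile_side, rows)
        for c0 in range(0, cols, tile_side):
            c1 = min(c0 + tile_side, cols)
            tiles.append(
                Tile(
                    tile_id=tid,
                    core_rows=(r0, r1),
                    core_cols=(c0, c1),
                    padded_rows=(max(0, r0 - overlap), min(rows, r1 + overlap)),
                    padded_cols=(max(0, c0 - overlap), min(cols, c1 + overlap)),
                )
            )
            tid += 1
    return TilePlan(grid_shape=(rows, cols), tile_side=tile_side, overlap=overlap,
                    tiles=tuple(tiles))


def merge_tiled(
    nvc: CategoricalGrid,
    cdl: CategoricalGrid,
    table: ClassMatchTable,
    scheme: MergedCodeScheme | None = None,
    config: MergeConfig | None = None,
    plan: TilePlan | None = None,
    progress: bool = False,
) -> MergeResult:
    """Run the merge per padded tile and mosaic the core windows.

    Exactly equivalent to the monolithic :func:`~spanmerge.merge.merge` for
    any valid plan (overlap ≥ radius); each tile is pure, so callers may
    parallelize externally.
    """
    config = config or MergeConfig()
    scheme = scheme or MergedCodeScheme(unresolved_code=config.unresolved_code)
    if plan is None:
        plan = plan_tiles(nvc.shape, cell_size=nvc.cell_size,
                          overlap=config.radius, radius=config.radius)
    if plan.grid_shape != nvc.shape:
        raise ValueError(f"plan is for shape {plan.grid_shape}, grid is {nvc.shape}")
    if plan.overlap < config.radius:
        raise ValueError(
            f"tile overlap ({plan.overlap} px) must be >= merge radius "
            f"({config.radius} px)"
        )
    nvc.check_aligned(cdl, "crop grid")

    out = np.empty(nvc.shape, dtype=np.int32)
    mismatch = np.empty(nvc.shape, dtype=bool)
    unresolved = np.empty(nvc.shape, dtype=bool)
    written = np.zeros(nvc.shape, dtype=bool)

    for tile in plan.tiles:
        pr, pc = tile.padded
        sub = merge(nvc.window(pr, pc), cdl.window(pr, pc), table, scheme, config)
        lr, lc = tile.core_in_padded
        cr, cc = tile.core
        out[cr, cc] = sub.merged.values[lr, lc]
        mismatch[cr, cc] = sub.mismatch_mask[lr, lc]
        unresolved[cr, cc] = sub.unresolved_mask[lr, lc]
        written[cr, cc] = True
        if progress:
            print(f"tile {tile.tile_id + 1}/{len(plan.tiles)} done")

    if not written.all():
        raise AssertionError("tile cores do not cover the grid")

    ag, _ = relation_grids(nvc, cdl, table)
    n_mis = int(mismatch.sum())
    n_unres = int(unresolved.sum())
    counts = {
        "passthrough": int((~ag).sum()),
        "matched": int(ag.sum()) - n_mis,
        "mismatched": n_mis,
        "resolved": n_mis - n_unres,
        "unresolved": n_unres,
    }
    return MergeResult(
        merged=nvc.like(out),
        mismatch_mask=mismatch,
        unresolved_mask=unresolved,
        counts=counts,
        resolved_step2=True,
    )
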