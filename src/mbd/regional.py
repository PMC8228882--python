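"""Tile-grid division of the segmented breast and regional/zonal percent density.

The segmented frame is divided into an 8-row x 6-column matrix of 48
equally sized rectangular sub-regions.  Each tile's regional PD is the
percentage of its pixels (or of its in-breast pixels, in mask mode) that
are radiodense.  Columns are grouped into three contiguous zones along
the chest-wall-to-nipple axis — posterior, middle, anterior — and each
zonal PD is the unweighted mean of the regional PDs in its column band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ZONES = ("posterior", "middle", "anterior")


class GridError(ValueError):
    """Raised when an image cannot be divided into the requested grid."""


@dataclass(frozen=True)
class TileGrid:
    """Partition of a ``height x width`` frame into ``rows x cols`` tiles.

    Tile extents are half-open pixel intervals
    ``[row_edges[i], row_edges[i+1]) x [col_edges[j], col_edges[j+1])``.
    Tile midpoints live in *tile units*: tile (i, j) has midpoint
    ``(i + 0.5, j + 0.5)``, so orthogonally adjacent midpoints are at
    distance 1 regardless of pixel size.
    """

    rows: int
    cols: int
    row_edges: tuple[int, ...]
    col_edges: tuple[int, ...]

    @property
    def height(self) -> int:
        return self.row_edges[-1]

    @property
    def width(self) -> int:
        return self.col_edges[-1]

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    def midpoints(self) -> np.ndarray:
        """(rows*cols, 2) array of tile midpoints in tile units, row-major."""
        ii, jj = np.meshgrid(
            np.arange(self.rows) + 0.5, np.arange(self.cols) + 0.5, indexing="ij"
        )
        return np.column_stack([ii.ravel(), jj.ravel()])

    def tile_areas(self) -> np.ndarray:
        """(rows, cols) array of tile pixel areas."""
        h = np.diff(self.row_edges)
        w = np.diff(self.col_edges)
        return np.outer(h, w)


def _edges(total: int, k: int) -> tuple[int, ...]:
    # base-size tiles first; the remainder pixels widen the last tiles
    base, rem = divmod(total, k)
    sizes = [base] * (k - rem) + [base + 1] * rem
    return tuple(np.concatenate([[0], np.cumsum(sizes)]).tolist())


def make_grid(height: int, width: int, rows: int = 8, cols: int = 6) -> TileGrid:
    """Partition a frame into ``rows x cols`` near-equal rectangular tiles.

    Tile heights (widths) differ by at most one pixel; remainder pixels go
    to the last tiles of each axis.  The tiles partition the frame exactly.
    """
    if rows < 1 or cols < 1:
        raise GridError("grid must have at least one row and one column")
    if height < rows or width < cols:
        raise GridError(
            f"image of size {height}x{width} too small for a {rows}x{cols} grid"
        )
    return TileGrid(rows, cols, _edges(height, rows), _edges(width, cols))


@dataclass(frozen=True)
class DensityGrid:
    """Regional PD matrix over a :class:`TileGrid`.

    ``pd[i, j]`` is the percent density of tile (i, j); ``denominators``
    records the per-tile denominator pixel count actually used (tile area
    in tile mode, in-mask pixel count in mask mode).  Tiles with a zero
    denominator report PD 0.
    """

    pd: np.ndarray
    denominators: np.ndarray
    grid: TileGrid
    denominator_mode: str


def _tile_counts(raster: np.ndarray, grid: TileGrid) -> np.ndarray:
    a = np.asarray(raster).astype(np.int64)
    rowsum = np.add.reduceat(a, grid.row_edges[:-1], axis=0)
    return np.add.reduceat(rowsum, grid.col_edges[:-1], axis=1)


def regional_pd(
    dense: np.ndarray,
    mask: np.ndarray,
    grid: TileGrid,
    denominator: str = "tile",
) -> DensityGrid:
    """Per-tile percent density of a segmented frame.

    Parameters
    ----------
    dense, mask
        Boolean rasters of shape ``(grid.height, grid.width)``; ``dense``
        marks radiodense pixels, ``mask`` in-breast pixels.
    denominator
        ``"tile"`` divides dense counts by whole tile areas (pixels outside
        the breast count as non-dense, matching a tile-splitter applied to
        the cropped binary image); ``"mask"`` divides by the in-breast pixel
        count of each tile, reporting 0 for breast-free tiles.
    """
    dense = np.asarray(dense, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    shape = (grid.height, grid.width)
    if dense.shape != shape or mask.shape != shape:
        raise GridError(f"raster shape does not match grid frame {shape}")
    if denominator not in ("tile", "mask"):
        raise ValueError("denominator must be 'tile' or 'mask'")
    num = _tile_counts(dense, grid)
    if denominator == "tile":
        denom = grid.tile_areas()
    else:
        denom = _tile_counts(mask, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        pd = np.where(denom > 0, 100.0 * num / np.maximum(denom, 1), 0.0)
    return DensityGrid(pd=pd, denominators=denom, grid=grid, denominator_mode=denominator)


@dataclass(frozen=True)
class ZoneDefinition:
    """Assignment of grid columns to the posterior/middle/anterior zones.

    ``columns[j]`` names the zone of column j.  Zones are contiguous column
    bands running from the chest wall (posterior) to the nipple (anterior).
    """

    columns: tuple[str, ...]
    chest_wall: str

    def zone_columns(self, zone: str) -> tuple[int, ...]:
        return tuple(j for j, z in enumerate(self.columns) if z == zone)


def default_zones(chest_wall: str = "left", cols: int = 6) -> ZoneDefinition:
    """Split the columns into three equal contiguous bands.

    With six columns and the chest wall at the left image edge, columns
    {0,1} are posterior, {2,3} middle and {4,5} anterior; a right chest
    wall mirrors the assignment.
    """
    if chest_wall not in ("left", "right"):
        raise ValueError("chest_wall must be 'left' or 'right'")
    if cols % 3 != 0:
        raise ValueError("default zones need a column count divisible by 3")
    band = cols // 3
    names = [z for z in ZONES for _ in range(band)]
    if chest_wall == "right":
        names = names[::-1]
    return ZoneDefinition(columns=tuple(names), chest_wall=chest_wall)


@dataclass(frozen=True)
class ZonalPD:
    posterior: float
    middle: float
    anterior: float

    def __getitem__(self, zone: str) -> float:
        return getattr(self, zone)


def zonal_pd(dgrid: DensityGrid, zones: ZoneDefinition) -> ZonalPD:
    """Unweighted mean of each zone's regional PDs (its 8x2 column band)."""
    if len(zones.columns) != dgrid.grid.cols:
        raise ValueError("zone definition does not cover the grid columns")
    out = {}
    for zone in ZONES:
        cols = zones.zone_columns(zone)
        if not cols:
            raise ValueError(f"zone {zone!r} has no columns")
        out[zone] = float(np.mean(dgrid.pd[:, cols]))
    return ZonalPD(**out)
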