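"""Unit geometry, per-minute resampling and dilated coverage rasters.

The care unit is discretized into square cells (1 m by default).  Each
workstation's instantaneous coverage is the cell it occupies expanded by a
Chebyshev dilation of ``d`` cells — a (2d+1)×(2d+1) block reaching in all
cardinal and diagonal directions — approximating the visual/functional range
of a caregiver near the workstation (2 m by default, consistent with the
personal/social zone of proxemics).  Coverage at a given minute is the union
over all workstations present that minute.

Cells are half-open intervals ``[k·s, (k+1)·s)`` identified by their minimum
corner; the grid origin sits at the minimum corner of the boundary's
bounding box, and rasters are indexed ``(row, col)`` = (y index, x index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon, box
import shapely

__all__ = [
    "UnitGrid",
    "MinuteFrame",
    "MinuteFrames",
    "CoverageRaster",
    "build_grid",
    "resample_per_minute",
    "occupied_cell",
    "dilate",
    "coverage_at_minute",
    "coverage_stack",
]


@dataclass(frozen=True)
class UnitGrid:
    """The ward geometry discretized into square cells.

    ``inside_mask[r, c]`` is True when the center of cell (r, c) falls inside
    the unit boundary; only inside cells contribute area or coverage.
    """

    origin: tuple[float, float]
    cell_size: float
    n_rows: int
    n_cols: int
    inside_mask: np.ndarray
    boundary: Polygon

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())

    @property
    def total_area(self) -> float:
        """Total unit area in m² (cell area × number of inside cells)."""
        return self.cell_size**2 * self.n_inside

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_rows, self.n_cols

    def occupied_cell(self, x: float, y: float) -> tuple[int, int] | None:
        return occupied_cell((x, y), self)

    def cells_to_raster(self, cells: Sequence[tuple[int, int]]) -> np.ndarray:
        raster = np.zeros(self.shape, dtype=bool)
        for r, c in cells:
            raster[r, c] = True
        return raster


@dataclass(frozen=True)
class MinuteFrame:
    """Positions (and staleness, in minutes) of every tag present at one minute."""

    minute_index: int
    positions: dict[str, tuple[float, float]]
    staleness: dict[str, int]


class MinuteFrames:
    """Dense per-minute positions for all tags, column-per-tag.

    ``x[i, j]`` / ``y[i, j]`` give tag ``tags[j]``'s carried-forward position
    at minute ``i`` (NaN when the tag is absent, i.e. stale beyond the
    carry-forward limit); ``staleness`` counts whole minutes since the tag's
    last emission.  Frame ``i`` covers the calendar minute ending at
    ``t0 + (i+1) minutes``.
    """

    def __init__(
        self,
        t0: pd.Timestamp,
        tags: Sequence[str],
        x: np.ndarray,
        y: np.ndarray,
        staleness: np.ndarray,
    ) -> None:
        self.t0 = t0
        self.tags = list(tags)
        self.x = x
        self.y = y
        self.staleness = staleness

    @property
    def n_minutes(self) -> int:
        return self.x.shape[0]

    def __len__(self) -> int:
        return self.n_minutes

    def timestamps(self) -> pd.DatetimeIndex:
        """Minute-end stamps for each frame."""
        return self.t0 + pd.to_timedelta(np.arange(1, self.n_minutes + 1), unit="min")

    def frame(self, i: int) -> MinuteFrame:
        present = ~np.isnan(self.x[i])
        positions = {
            tag: (float(self.x[i, j]), float(self.y[i, j]))
            for j, tag in enumerate(self.tags)
            if present[j]
        }
        staleness = {
            tag: int(self.staleness[i, j]) for j, tag in enumerate(self.tags) if present[j]
        }
        return MinuteFrame(minute_index=i, positions=positions, staleness=staleness)

    def __iter__(self) -> Iterator[MinuteFrame]:
        return (self.frame(i) for i in range(self.n_minutes))

    def slice(self, start: int, stop: int) -> "MinuteFrames":
        return MinuteFrames(
            t0=self.t0 + pd.Timedelta(minutes=start),
            tags=self.tags,
            x=self.x[start:stop],
            y=self.y[start:stop],
            staleness=self.staleness[start:stop],
        )


@dataclass(frozen=True)
class CoverageRaster:
    """Boolean per-cell coverage for one minute, aligned to a :class:`UnitGrid`."""

    minute_index: int
    covered: np.ndarray


def build_grid(
    boundary: Polygon | tuple[float, float] | Sequence[tuple[float, float]],
    cell_size: float = 1.0,
) -> UnitGrid:
    """Discretize a unit boundary into square cells.

    ``boundary`` may be a shapely polygon, a ``(width, height)`` rectangle
    anchored at the origin, or a vertex sequence.  A cell is inside the unit
    when its center lies within the boundary.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if isinstance(boundary, tuple) and len(boundary) == 2 and np.isscalar(boundary[0]):
        poly = box(0.0, 0.0, float(boundary[0]), float(boundary[1]))
    elif isinstance(boundary, Polygon):
        poly = boundary
    else:
        poly = Polygon(boundary)
    if poly.is_empty or not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate unit boundary")
    minx, miny, maxx, maxy = poly.bounds
    n_cols = int(np.ceil((maxx - minx) / cell_size - 1e-9))
    n_rows = int(np.ceil((maxy - miny) / cell_size - 1e-9))
    cx = minx + (np.arange(n_cols) + 0.5) * cell_size
    cy = miny + (np.arange(n_rows) + 0.5) * cell_size
    gx, gy = np.meshgrid(cx, cy)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(n_rows, n_cols)
    return UnitGrid(
        origin=(minx, miny),
        cell_size=cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
        inside_mask=inside,
        boundary=poly,
    )


def occupied_cell(position: tuple[float, float], grid: UnitGrid) -> tuple[int, int] | None:
    """Cell index for a position, or ``None`` when outside the unit.

    Half-open convention: ``floor((coord − origin) / cell_size)`` per axis, so
    a point exactly on a cell's upper edge belongs to the next cell.
    """
    x, y = position
    c = int(np.floor((x - grid.origin[0]) / grid.cell_size))
    r = int(np.floor((y - grid.origin[1]) / grid.cell_size))
    if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
        return None
    if not grid.inside_mask[r, c]:
        return None
    return r, c


def dilate(
    cells: Sequence[tuple[int, int]] | np.ndarray, d_cells: int, grid: UnitGrid
) -> np.ndarray:
    """Chebyshev dilation of occupied cells, clipped to the unit.

    Expands each occupied cell by ``d_cells`` in all cardinal and diagonal
    directions (a square (2d+1)² neighbourhood) and intersects the result
    with the unit's inside mask.
    """
    if d_cells < 0:
        raise ValueError("d_cells must be nonnegative")
    occ = cells if isinstance(cells, np.ndarray) and cells.dtype == bool else grid.cells_to_raster(cells)
    if d_cells == 0:
        return occ & grid.inside_mask
    structure = np.ones((2 * d_cells + 1, 2 * d_cells + 1), dtype=bool)
    return ndimage.binary_dilation(occ, structure=structure) & grid.inside_mask


def meters_to_cells(d_meters: float, grid: UnitGrid) -> int:
    """Map a dilation radius in meters to whole cells (``round(d / cell_size)``)."""
    return int(round(d_meters / grid.cell_size))


def resample_per_minute(
    stream,
    grid: UnitGrid,
    max_staleness: int = 2,
    n_minutes: int | None = None,
    t0: pd.Timestamp | None = None,
) -> MinuteFrames:
    """Resample a (filtered) position stream onto a per-minute time base.

    For each calendar minute, a tag's position is its last emission at or
    before the minute's end, carried forward while the tag's staleness (whole
    minutes since that emission) does not exceed ``max_staleness``; staler
    tags are absent.  The default limit of 2 minutes tolerates one missed
    stationary beacon while treating longer silences as true absence.
    """
    df = stream.df
    if t0 is None:
        t0 = df["t"].min().floor("min")
    end = df["t"].max()
    if n_minutes is None:
        n_minutes = int((end - t0) // pd.Timedelta(minutes=1)) + 1
    tags = sorted(df["tag_id"].unique())
    k = len(tags)
    x = np.full((n_minutes, k), np.nan)
    y = np.full((n_minutes, k), np.nan)
    staleness = np.full((n_minutes, k), -1, dtype=np.int32)
    minutes = np.arange(n_minutes)
    for j, tag in enumerate(tags):
        g = df[df["tag_id"] == tag]
        m = ((g["t"] - t0) // pd.Timedelta(minutes=1)).to_numpy(np.int64)
        keep = (m >= 0) & (m < n_minutes)
        m = m[keep]
        gx = g["x"].to_numpy(float)[keep]
        gy = g["y"].to_numpy(float)[keep]
        if len(m) == 0:
            continue
        # last emission within each minute, then carry forward
        last_in_minute = np.full(n_minutes, -1, dtype=np.int64)
        last_in_minute[m] = np.arange(len(m))  # ascending t ⇒ final write wins
        has = last_in_minute >= 0
        last_minute = np.where(has, minutes, -1)
        last_minute = np.maximum.accumulate(last_minute)
        valid = last_minute >= 0
        stale = np.where(valid, minutes - last_minute, -1)
        present = valid & (stale <= max_staleness)
        src = last_in_minute[np.where(valid, last_minute, 0)]
        x[present, j] = gx[src[present]]
        y[present, j] = gy[src[present]]
        staleness[present, j] = stale[present]
    return MinuteFrames(t0=t0, tags=tags, x=x, y=y, staleness=staleness)


def coverage_at_minute(frame: MinuteFrame, d_cells: int, grid: UnitGrid) -> CoverageRaster:
    """Union of dilated occupied cells over all tags present in one frame."""
    cells = []
    for tag, (px, py) in frame.positions.items():
        cell = occupied_cell((px, py), grid)
        if cell is not None:
            cells.append(cell)
    return CoverageRaster(minute_index=frame.minute_index, covered=dilate(cells, d_cells, grid))


def coverage_stack(frames: MinuteFrames, d_cells: int, grid: UnitGrid) -> np.ndarray:
    """Boolean coverage rasters for every minute, shape (n_minutes, n_rows, n_cols).

    Vectorized equivalent of mapping :func:`coverage_at_minute` over frames.
    """
    n = frames.n_minutes
    cov = np.zeros((n, grid.n_rows, grid.n_cols), dtype=bool)
    x0, y0 = grid.origin
    s = grid.cell_size
    offsets = [(dr, dc) for dr in range(-d_cells, d_cells + 1) for dc in range(-d_cells, d_cells + 1)]
    for j in range(len(frames.tags)):
        present = ~np.isnan(frames.x[:, j])
        if not present.any():
            continue
        mi = np.flatnonzero(present)
        c = np.floor((frames.x[mi, j] - x0) / s).astype(np.int64)
        r = np.floor((frames.y[mi, j] - y0) / s).astype(np.int64)
        in_range = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
        mi, r, c = mi[in_range], r[in_range], c[in_range]
        in_unit = grid.inside_mask[r, c]
        mi, r, c = mi[in_unit], r[in_unit], c[in_unit]
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            ok = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_cols)
            cov[mi[ok], rr[ok], cc[ok]] = True
    cov &= grid.inside_mask
    return cov


def raster_to_csv(raster: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, raster.astype(int), fmt="%d", delimiter=",")


def raster_heatmap(raster: np.ndarray, path: str | Path, title: str = "") -> None:
    """Render a raster as a heatmap image for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(raster, origin="lower", cmap="viridis")
    ax.set_xlabel("x cell")
    ax.set_ylabel("y cell")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
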