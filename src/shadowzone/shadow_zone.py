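"""Per-minute spatial shadow-zone tracking.

A cell is in *spatial shadow* at minute t when it has been outside every
workstation's dilated coverage area for at least T consecutive minutes ending
at t (T = 60 by default, the conventional rounding interval).  The per-minute
*percentage of spatial shadow zone* is the shadow area divided by the total
unit area, ×100.

The tracker is incremental: one uncovered-minutes counter per cell, reset to
zero the minute the cell is covered, incremented otherwise.  Counters start
at zero at stream start (cells presumed recently visited); a warm-up policy
can mask the first T minutes instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid_coverage import CoverageRaster, MinuteFrames, UnitGrid, coverage_stack

__all__ = [
    "ShadowParams",
    "ShadowState",
    "ShadowSeries",
    "update_shadow",
    "shadow_series",
    "sensitivity_surface",
    "DEFAULT_D_LIST",
    "DEFAULT_T_LIST",
]

DEFAULT_D_LIST = (1, 2, 3, 4)
DEFAULT_T_LIST = (15, 30, 45, 60, 75, 90)


@dataclass(frozen=True)
class ShadowParams:
    """Shadow-zone definition parameters.

    ``d_cells`` is the Chebyshev dilation radius of workstation coverage (in
    cells; 2 cells ≈ 2 m at the default 1 m grid), ``T_minutes`` the
    persistence threshold a cell must stay uncovered to count as shadow.
    """

    d_cells: int = 2
    T_minutes: int = 60
    warmup_policy: str = "report_all"  # or "mask_first_T"

    def __post_init__(self) -> None:
        if self.T_minutes < 1:
            raise ValueError("T_minutes must be >= 1")
        if self.d_cells < 0:
            raise ValueError("d_cells must be >= 0")
        if self.warmup_policy not in ("report_all", "mask_first_T"):
            raise ValueError(f"unknown warmup_policy {self.warmup_policy!r}")


@dataclass(frozen=True)
class ShadowState:
    """Per-cell consecutive-uncovered-minute counters and the derived mask."""

    uncovered_minutes: np.ndarray
    params: ShadowParams

    @classmethod
    def initial(cls, grid: UnitGrid, params: ShadowParams) -> "ShadowState":
        return cls(uncovered_minutes=np.zeros(grid.shape, dtype=np.int32), params=params)

    @property
    def shadow_mask(self) -> np.ndarray:
        return self.uncovered_minutes >= self.params.T_minutes

    def percent_shadow(self, grid: UnitGrid) -> float:
        return 100.0 * float((self.shadow_mask & grid.inside_mask).sum()) / grid.n_inside


def update_shadow(state: ShadowState, coverage: CoverageRaster, params: ShadowParams | None = None) -> ShadowState:
    """Advance the shadow tracker by one minute of coverage.

    Covered cells reset their counter to zero; uncovered cells accumulate.  A
    cell therefore leaves shadow the minute it is covered and re-enters only
    after another full T uncovered minutes.
    """
    params = params or state.params
    if coverage.covered.shape != state.uncovered_minutes.shape:
        raise ValueError("coverage raster does not match the tracker's grid")
    counters = np.where(coverage.covered, 0, state.uncovered_minutes + 1).astype(np.int32)
    return ShadowState(uncovered_minutes=counters, params=params)


@dataclass(frozen=True)
class ShadowSeries:
    """Minute-indexed percentage of spatial shadow zone."""

    percent: np.ndarray
    params: ShadowParams
    t0: pd.Timestamp

    @property
    def n_minutes(self) -> int:
        return len(self.percent)

    def timestamps(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(np.arange(1, self.n_minutes + 1), unit="min")

    @property
    def analyzed(self) -> np.ndarray:
        """Mask of minutes retained for analysis under the warm-up policy."""
        keep = np.ones(self.n_minutes, dtype=bool)
        if self.params.warmup_policy == "mask_first_T":
            keep[: self.params.T_minutes] = False
        return keep

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute": np.arange(self.n_minutes),
                "timestamp": self.timestamps(),
                "percent_shadow": self.percent,
                "d_cells": self.params.d_cells,
                "T_minutes": self.params.T_minutes,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _shadow_percent_counts(
    cov: np.ndarray, inside_mask: np.ndarray, T_list: Sequence[int]
) -> np.ndarray:
    """Shadow-cell counts per minute for several persistence thresholds.

    One pass of the incremental counters over a coverage stack, thresholded
    at each T in ``T_list``; returns shape (n_minutes, len(T_list)).
    """
    n = cov.shape[0]
    inside_flat = np.flatnonzero(inside_mask.ravel())
    cov_in = cov.reshape(n, -1)[:, inside_flat]
    counters = np.zeros(len(inside_flat), dtype=np.int32)
    T_arr = np.asarray(sorted(set(int(t) for t in T_list)), dtype=np.int32)
    order = {int(t): i for i, t in enumerate(T_arr)}
    counts = np.empty((n, len(T_arr)), dtype=np.int64)
    for t in range(n):
        counters = np.where(cov_in[t], 0, counters + 1)
        # counters sorted against thresholds via searchsorted on the sorted counter copy
        counts[t] = len(counters) - np.searchsorted(np.sort(counters), T_arr, side="left")
    # restore caller's T order
    idx = [order[int(t)] for t in T_list]
    return counts[:, idx]


def shadow_series(
    frames: MinuteFrames, grid: UnitGrid, params: ShadowParams | None = None
) -> ShadowSeries:
    """Stream the shadow tracker over per-minute frames.

    Minutes with no present workstation still advance the counters — absence
    is precisely what shadow measures.
    """
    params = params or ShadowParams()
    if frames.n_minutes == 0:
        return ShadowSeries(percent=np.empty(0), params=params, t0=frames.t0)
    cov = coverage_stack(frames, params.d_cells, grid)
    counts = _shadow_percent_counts(cov, grid.inside_mask, [params.T_minutes])[:, 0]
    percent = 100.0 * counts / grid.n_inside
    return ShadowSeries(percent=percent, params=params, t0=frames.t0)


def sensitivity_surface(
    frames: MinuteFrames,
    grid: UnitGrid,
    d_list: Sequence[int] = DEFAULT_D_LIST,
    T_list: Sequence[int] = DEFAULT_T_LIST,
    warmup_policy: str = "report_all",
) -> dict[tuple[int, int], ShadowSeries]:
    """Shadow series for every (dilation, persistence) parameter pair.

    A single coverage pass per dilation radius feeds shared counters that are
    thresholded at every T, so the (d, T) grid costs little more than
    len(d_list) plain series.
    """
    out: dict[tuple[int, int], ShadowSeries] = {}
    for d in d_list:
        cov = coverage_stack(frames, d, grid)
        counts = _shadow_percent_counts(cov, grid.inside_mask, T_list)
        for j, T in enumerate(T_list):
            params = ShadowParams(d_cells=d, T_minutes=int(T), warmup_policy=warmup_policy)
            out[(int(d), int(T))] = ShadowSeries(
                percent=100.0 * counts[:, j] / grid.n_inside, params=params, t0=frames.t0
            )
    return out


def surface_to_frame(surface: dict[tuple[int, int], ShadowSeries]) -> pd.DataFrame:
    """Long-format export of a sensitivity surface, keyed by (d, T)."""
    parts = []
    for (d, T), series in sorted(surface.items()):
        f = series.to_frame()
        parts.append(f)
    return pd.concat(parts, ignore_index=True)
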