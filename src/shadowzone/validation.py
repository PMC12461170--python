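"""Positional-accuracy validation against a ground-truth route.

A tagged workstation is pushed along a predefined, marked polyline at walking
speed while the positioning system records estimates.  Each estimate's error
is its planar distance to the ground truth: by default the nearest point on
the route polyline (no per-point truth timestamps are assumed), or, when a
paired truth position is available for every estimate, the distance to that
corresponding point.  The error sample is summarized by its mean, SD,
normal-approximation 95% CI, empirical quantiles and a CDF table/plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

__all__ = [
    "GroundTruthRoute",
    "ErrorDistribution",
    "point_to_polyline_distance",
    "error_distribution",
]


@dataclass(frozen=True)
class GroundTruthRoute:
    """An ordered open polyline of (x, y) vertices in meters."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
            raise ValueError("route needs at least 2 planar vertices")
        if (np.linalg.norm(np.diff(v, axis=0), axis=1) == 0).any():
            raise ValueError("route has coincident consecutive vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruthRoute":
        df = pd.read_csv(path)
        return cls(vertices=df[["x", "y"]].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.vertices, columns=["x", "y"]).to_csv(path, index=False)

    def sample(self, n: int) -> np.ndarray:
        """n points evenly spaced by arc length along the route."""
        line = self.line
        dists = np.linspace(0.0, line.length, n)
        pts = [line.interpolate(d) for d in dists]
        return np.array([[p.x, p.y] for p in pts])


def point_to_polyline_distance(p: tuple[float, float], route: GroundTruthRoute) -> float:
    """Minimum Euclidean distance from a point to any segment of the route.

    The perpendicular projection is clamped to segment endpoints, so a point
    beyond a terminal vertex is scored against that vertex.
    """
    return float(Point(p).distance(route.line))


@dataclass(frozen=True)
class ErrorDistribution:
    """Summary of a sample of nonnegative positional errors (meters)."""

    errors: np.ndarray

    def __post_init__(self) -> None:
        e = np.sort(np.asarray(self.errors, dtype=float))
        if len(e) == 0:
            raise ValueError("empty error sample")
        if (e < 0).any():
            raise ValueError("errors must be nonnegative")
        object.__setattr__(self, "errors", e)

    @property
    def n(self) -> int:
        return len(self.errors)

    @property
    def mean(self) -> float:
        return float(self.errors.mean())

    @property
    def sd(self) -> float:
        return float(self.errors.std(ddof=1)) if self.n > 1 else 0.0

    @property
    def ci95(self) -> tuple[float, float]:
        se = self.sd / np.sqrt(self.n)
        return (self.mean - 1.96 * se, self.mean + 1.96 * se)

    def quantile(self, q: float | Sequence[float]) -> float | np.ndarray:
        """Empirical quantile with linear interpolation between order statistics."""
        out = np.quantile(self.errors, q, method="linear")
        return float(out) if np.isscalar(q) else out

    def cdf_table(self) -> pd.DataFrame:
        """Empirical CDF: P(error ≤ e) at each observed error."""
        return pd.DataFrame(
            {"error_m": self.errors, "cum_prob": np.arange(1, self.n + 1) / self.n}
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "n": self.n,
            "mean_m": self.mean,
            "sd_m": self.sd,
            "ci95_m": [lo, hi],
            "p50_m": self.quantile(0.5),
            "p80_m": self.quantile(0.8),
            "p95_m": self.quantile(0.95),
        }

    def plot_cdf(self, path: str | Path, mark_quantile: float | None = 0.8) -> None:
        """CDF plot of error distances, optionally marking one quantile."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        table = self.cdf_table()
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.step(table["error_m"], table["cum_prob"], where="post")
        if mark_quantile is not None:
            q = self.quantile(mark_quantile)
            ax.axvline(q, ls="--", c="gray")
            ax.axhline(mark_quantile, ls="--", c="gray")
            ax.annotate(f"{q:.3f} m", (q, mark_quantile), textcoords="offset points", xytext=(5, -12))
        ax.set_xlabel("positional error (m)")
        ax.set_ylabel("cumulative probability")
        ax.set_ylim(0, 1.02)
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def error_distribution(
    estimates, route: GroundTruthRoute, truth: np.ndarray | None = None
) -> ErrorDistribution:
    """Per-point positional errors of a stream of estimates.

    ``estimates`` is a PositionStream or an (n, 2) array.  With ``truth``
    (an (n, 2) array of corresponding ground-truth positions, in estimate
    order) each error is the paired Euclidean distance; otherwise it is the
    distance to the nearest point on the route polyline.
    """
    if hasattr(estimates, "df"):
        xy = estimates.df[["x", "y"]].to_numpy(float)
    else:
        xy = np.asarray(estimates, dtype=float).reshape(-1, 2)
    if len(xy) < 2:
        raise ValueError("need at least 2 positional estimates")
    if truth is not None:
        truth = np.asarray(truth, dtype=float).reshape(-1, 2)
        if truth.shape != xy.shape:
            raise ValueError("truth must pair one position per estimate")
        errors = np.linalg.norm(xy - truth, axis=1)
    else:
        pts = shapely.points(xy)
        errors = shapely.distance(pts, route.line)
    return ErrorDistribution(errors=errors)
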