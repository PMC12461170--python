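"""Reading, writing and quality control of RTLS position streams.

The raw input is a delimited text stream of tag emissions (tag id, timestamp,
planar coordinates in meters).  Tags on mobile workstations beacon at 1 Hz
while the workstation moves and drop to one emission per minute while it is
parked, so the stream mixes two sampling regimes.  This module sorts and
de-duplicates the stream, applies the isolated-outlier noise rule (a point
further than a jump threshold from *both* of its temporal neighbours), and
derives data-quality metrics: the overall noise rate and an hourly missing
rate computed against the regime-aware expected emission count.

All analysis here is planar: a ``z`` column is read and carried through, but
distances ignore it (the unit is single-storey).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionStream",
    "EventRecord",
    "Shift",
    "ShiftSchedule",
    "QualityReport",
    "EmptyStreamError",
    "read_positions",
    "write_positions",
    "read_events",
    "write_events",
    "filter_noise",
    "compute_noise_rate",
    "missing_rate_per_hour",
    "DEFAULT_JUMP_THRESHOLD",
]

#: Isolated-outlier displacement threshold in meters.
DEFAULT_JUMP_THRESHOLD = 2.5

EVENT_KINDS = ("fall", "icu_transfer")


class EmptyStreamError(ValueError):
    """Raised when a position file contains no usable records."""


@dataclass(frozen=True)
class PositionStream:
    """An ordered, de-duplicated sequence of tag emissions.

    ``df`` has columns ``tag_id`` (str), ``t`` (tz-aware UTC datetime),
    ``x``, ``y`` (meters) and optionally ``z``; it is sorted by
    ``(tag_id, t)`` with duplicate ``(tag_id, t)`` pairs resolved by keeping
    the first occurrence.
    """

    df: pd.DataFrame
    n_dropped: int = 0
    n_duplicates: int = 0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_dropped: int = 0) -> "PositionStream":
        df = df.copy()
        if df["t"].dt.tz is None:
            df["t"] = df["t"].dt.tz_localize("UTC")
        else:
            df["t"] = df["t"].dt.tz_convert("UTC")
        df = df.sort_values(["tag_id", "t"], kind="stable")
        before = len(df)
        df = df.drop_duplicates(subset=["tag_id", "t"], keep="first")
        df = df.reset_index(drop=True)
        if not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
            raise ValueError("non-finite coordinates in position stream")
        return cls(df=df, n_dropped=n_dropped, n_duplicates=before - len(df))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tags(self) -> list[str]:
        return sorted(self.df["tag_id"].unique().tolist())

    @property
    def time_span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.df["t"].min(), self.df["t"].max()

    def per_tag(self, tag_id: str) -> pd.DataFrame:
        return self.df[self.df["tag_id"] == tag_id]


@dataclass(frozen=True)
class EventRecord:
    """A clinical event: a hospital fall or an ICU transfer."""

    kind: str
    t: pd.Timestamp
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")


@dataclass(frozen=True)
class Shift:
    name: str
    start: datetime.time
    end: datetime.time
    patient_to_nurse_ratio: float

    def contains_hour(self, hour: int) -> bool:
        s, e = self.start.hour, self.end.hour
        if s < e:
            return s <= hour < e
        return hour >= s or hour < e  # wraps midnight


@dataclass(frozen=True)
class ShiftSchedule:
    """Nursing shifts partitioning the 24 h day, with staffing ratios.

    The default mirrors a three-shift acute-care roster: 7 patients per
    nurse on days, 9 on evenings, 10 on nights.
    """

    shifts: tuple[Shift, ...]

    def __post_init__(self) -> None:
        covered = [self.shift_at(h) for h in range(24)]
        for h, s in enumerate(covered):
            if s is None:
                raise ValueError(f"shift schedule does not cover hour {h}")
        if any(s.patient_to_nurse_ratio <= 0 for s in self.shifts):
            raise ValueError("patient-to-nurse ratios must be positive")

    def shift_at(self, hour: int) -> Shift | None:
        for s in self.shifts:
            if s.contains_hour(hour):
                return s
        return None

    def ratio_at(self, when: pd.Timestamp | int) -> float:
        hour = when if isinstance(when, (int, np.integer)) else when.hour
        shift = self.shift_at(int(hour))
        assert shift is not None
        return shift.patient_to_nurse_ratio

    def ratios_by_hour(self) -> np.ndarray:
        return np.array([self.ratio_at(h) for h in range(24)], dtype=float)

    @classmethod
    def default(cls) -> "ShiftSchedule":
        return cls(
            shifts=(
                Shift("day", datetime.time(7), datetime.time(15), 7.0),
                Shift("evening", datetime.time(15), datetime.time(23), 9.0),
                Shift("night", datetime.time(23), datetime.time(7), 10.0),
            )
        )

    @classmethod
    def from_config(cls, path: str | Path) -> "ShiftSchedule":
        """Read ``name,start_hour,end_hour,ratio`` lines (# comments allowed)."""
        shifts = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end, ratio = [p.strip() for p in line.split(",")]
            shifts.append(
                Shift(name, datetime.time(int(start) % 24), datetime.time(int(end) % 24), float(ratio))
            )
        return cls(shifts=tuple(shifts))

    def to_config(self, path: str | Path) -> None:
        lines = ["# name,start_hour,end_hour,patients_per_nurse"]
        for s in self.shifts:
            lines.append(f"{s.name},{s.start.hour},{s.end.hour},{s.patient_to_nurse_ratio:g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class QualityReport:
    """Data-quality metrics for a position stream."""

    total_points: int = 0
    noise_points: int = 0
    noise_rate: float = 0.0
    odds_denominator: int | None = None
    hourly_missing: pd.Series | None = None
    missing_mean: float | None = None
    missing_ci95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "total_points": int(self.total_points),
            "noise_points": int(self.noise_points),
            "noise_rate": float(self.noise_rate),
            "odds_denominator": None if self.odds_denominator is None else int(self.odds_denominator),
            "missing_mean": None if self.missing_mean is None else float(self.missing_mean),
            "missing_ci95": None if self.missing_ci95 is None else [float(v) for v in self.missing_ci95],
        }
        if self.hourly_missing is not None:
            d["hourly_missing"] = {str(k): float(v) for k, v in self.hourly_missing.items()}
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# file I/O


def read_positions(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    timestamp_format: str | None = None,
    tz: str = "UTC",
) -> PositionStream:
    """Read a delimited position file into a sorted, de-duplicated stream.

    Parameters
    ----------
    path
        CSV file with a header; default columns ``tag_id,timestamp,x,y[,z]``.
    columns
        Optional remapping from the file's column names to the canonical
        ones, e.g. ``{"id": "tag_id", "time": "timestamp"}``.
    timestamp_format
        Optional explicit ``strftime`` pattern; default ISO-8601 parsing.
    tz
        Time zone of naive input timestamps (converted to UTC internally).

    Malformed rows (unparseable timestamps or coordinates) are dropped and
    counted in ``PositionStream.n_dropped``.
    """
    raw = pd.read_csv(path, dtype={0: str})
    if columns:
        raw = raw.rename(columns=dict(columns))
    if raw.empty:
        raise EmptyStreamError(f"{path}: no records")
    required = {"tag_id", "timestamp", "x", "y"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    t = pd.to_datetime(raw["timestamp"], format=timestamp_format, errors="coerce", utc=False)
    if t.dt.tz is None:
        t = t.dt.tz_localize(tz, nonexistent="NaT", ambiguous="NaT")
    t = t.dt.tz_convert("UTC")
    x = pd.to_numeric(raw["x"], errors="coerce")
    y = pd.to_numeric(raw["y"], errors="coerce")
    bad = t.isna() | x.isna() | y.isna()
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()  # +2: header + 1-based
        warnings.warn(f"{path}: dropped {int(bad.sum())} malformed rows (lines {lines[:10]}...)")
    df = pd.DataFrame({"tag_id": raw["tag_id"].astype(str), "t": t, "x": x, "y": y})
    if "z" in raw.columns:
        df["z"] = pd.to_numeric(raw["z"], errors="coerce")
    df = df[~bad]
    if df.empty:
        raise EmptyStreamError(f"{path}: no parseable records")
    return PositionStream.from_dataframe(df, n_dropped=int(bad.sum()))


def write_positions(stream: PositionStream, path: str | Path) -> None:
    out = stream.df.copy()
    out = out.rename(columns={"t": "timestamp"})
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def read_events(path: str | Path, tz: str = "UTC") -> pd.DataFrame:
    """Read an event log CSV ``kind,timestamp,subtype`` → DataFrame(kind, t, subtype)."""
    raw = pd.read_csv(path, dtype=str).fillna("")
    bad_kinds = set(raw["kind"]) - set(EVENT_KINDS)
    if bad_kinds:
        raise ValueError(f"{path}: unknown event kinds {sorted(bad_kinds)}")
    t = pd.to_datetime(raw["timestamp"], utc=False)
    if t.dt.tz is None:
        t = t.dt.tz_localize(tz)
    return pd.DataFrame({"kind": raw["kind"], "t": t.dt.tz_convert("UTC"), "subtype": raw["subtype"]})


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out = out.rename(columns={"t": "timestamp"})
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out[["kind", "timestamp", "subtype"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality control


def filter_noise(
    stream: PositionStream, jump_threshold: float = DEFAULT_JUMP_THRESHOLD
) -> tuple[PositionStream, QualityReport]:
    """Remove isolated spurious displacements from a sorted stream.

    A record is classified as noise iff its planar distance to *both* the
    preceding and the following record of the same tag exceeds
    ``jump_threshold`` (default 2.5 m).  A point far from only one neighbour
    is a legitimate move, and a run of two or more displaced points is a
    sustained excursion, so neither is flagged; the first and last record of
    each tag are never flagged.  All flags are evaluated simultaneously
    before any removal, which makes the filter idempotent.
    """
    if jump_threshold <= 0:
        raise ValueError("jump_threshold must be positive")
    df = stream.df
    flags = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("tag_id", sort=False).indices.items():
        if len(idx) < 3:
            warnings.warn("tag with fewer than 3 records: noise flagging not possible")
            continue
        xy = df.iloc[idx][["x", "y"]].to_numpy(float)
        step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
        far_prev = np.r_[False, step > jump_threshold]
        far_next = np.r_[step > jump_threshold, False]
        flags[idx] = far_prev & far_next
    kept = df[~flags].reset_index(drop=True)
    filtered = PositionStream(df=kept, n_dropped=stream.n_dropped, n_duplicates=stream.n_duplicates)
    rate, denom = compute_noise_rate(len(df), int(flags.sum())) if len(df) else (0.0, None)
    report = QualityReport(
        total_points=len(df),
        noise_points=int(flags.sum()),
        noise_rate=rate,
        odds_denominator=denom,
    )
    return filtered, report


def compute_noise_rate(total_points: int, noise_points: int) -> tuple[float, int | None]:
    """Noise fraction and its "1 in N" odds denominator.

    Returns ``(noise_points / total_points, round(total_points / noise_points))``;
    the denominator is ``None`` when there is no noise.
    """
    if total_points <= 0:
        raise ValueError("total_points must be positive")
    if not 0 <= noise_points <= total_points:
        raise ValueError("noise_points must lie in [0, total_points]")
    fraction = noise_points / total_points
    denominator = None if noise_points == 0 else round(total_points / noise_points)
    return fraction, denominator


def _gap_expected_emissions(
    dt: np.ndarray,
    disp: np.ndarray,
    stationary_gap: tuple[float, float],
    stationary_displacement: float,
) -> np.ndarray:
    """Expected emission count across each inter-emission gap.

    Tags beacon at 1 Hz in motion and once per minute when parked.  A gap is
    attributed to the stationary regime when its duration is consistent with
    the one-per-minute cadence or the tag barely moved across it; stationary
    gaps expect one emission per 60 s, motion gaps one per second.
    """
    lo, hi = stationary_gap
    stationary = ((dt >= lo) & (dt <= hi)) | (disp < stationary_displacement)
    return np.where(stationary, dt / 60.0, dt)


def missing_rate_per_hour(
    stream: PositionStream,
    stationary_gap: tuple[float, float] = (45.0, 75.0),
    stationary_displacement: float = 0.5,
) -> QualityReport:
    """Hourly missing-data rate against the regime-aware expected count.

    For every tag-hour the expected number of emissions is accumulated gap by
    gap (1 Hz during motion, 1/min while stationary — the stationary regime
    is thereby excluded from the 1 Hz expectation); the missing rate is
    ``1 − observed/expected`` clipped to [0, 1].  Returns the pooled hourly
    series with its mean and normal-approximation 95% CI.
    """
    df = stream.df
    t0, t1 = stream.time_span
    if (t1 - t0) < pd.Timedelta(hours=1):
        raise ValueError("stream must span at least one hour")
    rows = []
    for tag, g in df.groupby("tag_id", sort=False):
        if len(g) < 2:
            continue
        tsec = g["t"].astype("int64").to_numpy() / 1e9
        xy = g[["x", "y"]].to_numpy(float)
        dt = np.diff(tsec)
        disp = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
        expected = _gap_expected_emissions(dt, disp, stationary_gap, stationary_displacement)
        # each gap contributes one observed arrival; attribute it to the hour
        # in which the gap starts (gaps spanning an hour boundary are rare)
        hour = g["t"].dt.floor("h").to_numpy()[:-1]
        per_hour = pd.DataFrame({"hour": hour, "expected": expected, "observed": 1.0})
        agg = per_hour.groupby("hour").sum()
        agg["tag_id"] = tag
        rows.append(agg.reset_index())
    if not rows:
        raise ValueError("no tag has enough records for a missing-rate estimate")
    agg = pd.concat(rows, ignore_index=True)
    usable = agg[agg["expected"] > 0]
    if len(usable) < len(agg):
        warnings.warn(f"excluded {len(agg) - len(usable)} tag-hours with zero expected emissions")
    rate = (1.0 - usable["observed"] / usable["expected"]).clip(0.0, 1.0)
    hourly = pd.Series(rate.to_numpy(), index=pd.MultiIndex.from_frame(usable[["tag_id", "hour"]]))
    mean = float(hourly.mean())
    n = len(hourly)
    se = float(hourly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return QualityReport(
        hourly_missing=hourly,
        missing_mean=mean,
        missing_ci95=(mean - 1.96 * se, mean + 1.96 * se),
    )
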