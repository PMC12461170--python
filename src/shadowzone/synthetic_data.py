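"""Synthetic RTLS streams, quality artifacts and event logs.

The generator emulates the observational setting end to end so every pipeline
stage can be exercised without real data: mobile workstations move bed to bed
through a rectangular acute-care unit following a semi-Markov process
(bedside dwells alternating with straight-line transits at walking speed),
tags beacon at 1 Hz in motion and once per minute while parked, isolated
positional jumps and missing emissions are injected at configurable rates,
and per-minute fall / ICU-transfer events are drawn from logistic models on
the true shadow percentage.  The pre-corruption truth (clean stream, true
shadow series, injected artifact indices, event coefficients) is recorded so
recovery can be scored exactly.

An optional two-pass mechanism emulates intensified bedside care before ICU
transfers: for each transfer, one workstation's emissions in the preceding
hour are replaced by stationary beacons at a patient bed, which depresses the
shadow percentage in that window and reproduces the inverse shadow–ICU
association without making low shadow protective.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .grid_coverage import MinuteFrames, UnitGrid, build_grid, resample_per_minute
from .rtls_io import PositionStream, ShiftSchedule
from .shadow_zone import ShadowParams, ShadowSeries, shadow_series

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "default_bed_layout",
    "simulate_trajectories",
    "corrupt",
    "simulate_events",
    "calibrate_intercept",
    "simulate_study",
    "score_noise_recovery",
]

#: Study-scale event frequencies: 8 falls and 89 ICU transfers per 210 days.
STUDY_MINUTES = 210 * 1440
FALL_RATE_PER_MINUTE = 8 / STUDY_MINUTES
ICU_RATE_PER_MINUTE = 89 / STUDY_MINUTES

FALLER_TYPES = (("patient", 6 / 8), ("family", 1 / 8), ("staff", 1 / 8))
ICU_CAUSES = (
    ("advanced_respiratory_support", 45 / 89),
    ("circulatory_support", 35 / 89),
    ("cardiac_arrest", 4 / 89),
    ("neurological_monitoring", 3 / 89),
    ("acute_coronary_syndrome", 1 / 89),
    ("diabetic_ketoacidosis", 1 / 89),
)


def default_bed_layout(width: float, height: float, n_beds: int) -> np.ndarray:
    """Beds in 4 rows spanning the unit (10 per row at the 40-bed default)."""
    n_rows = 4
    per_row = int(np.ceil(n_beds / n_rows))
    xs = np.linspace(0.05 * width, 0.95 * width, per_row)
    ys = np.linspace(0.125 * height, 0.875 * height, n_rows)
    coords = [(x, y) for y in ys for x in xs]
    return np.array(coords[:n_beds])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated unit.

    Defaults reproduce the observed setting: a 400 m² (20×20 m) unit with 40
    beds, 4 mobile workstations moving at 0.5–1 m/s, tags beaconing at 1 Hz
    in motion and 1/min when parked, an isolated-jump noise probability of
    0.226%, and fall/ICU log-odds linear in the shadow percentage with
    slopes ln(1.02) and ln(0.99) per percentage point, intercepts calibrated
    to 8 falls and 89 transfers per 210 days.
    """

    seed: int = 0
    days: float = 210.0
    start: str = "2024-08-04"
    width: float = 20.0
    height: float = 20.0
    n_beds: int = 40
    n_workstations: int = 4
    speed_range: tuple[float, float] = (0.5, 1.0)
    # bedside dwell ~ lognormal(median 60 min, sigma 0.6); long parked spells
    # with occasional local rounds keep ~3/4 of the unit in shadow, the
    # occupancy level observed in hybrid central/mobile-station units
    dwell_median_minutes: float = 60.0
    dwell_sigma: float = 0.6
    p_central: float = 0.5  # probability a move returns to the central station
    p_local: float = 0.8  # otherwise: prefer beds within move_locality_m
    move_locality_m: float = 5.0
    emission_moving_hz: float = 1.0
    emission_stationary_s: float = 60.0
    noise_prob: float = 0.00226
    noise_jump_range: tuple[float, float] = (4.0, 10.0)  # gross multipath outliers
    missing_prob: float = 0.01
    beta_shadow_fall: float = math.log(1.02)
    beta_shadow_icu: float = math.log(0.99)
    beta0_fall: float | None = None  # None => calibrated by bisection
    beta0_icu: float | None = None
    fall_rate_inflation: float = 1.0  # >1 boosts baseline rate for power studies
    icu_rate_inflation: float = 1.0
    simulate_icu: bool = True
    icu_clustering: bool = True
    clustering_minutes: int = 60
    d_cells: int = 2
    T_minutes: int = 60
    max_staleness: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.noise_prob <= 1 or not 0 <= self.missing_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.speed_range[0] <= 0 or self.speed_range[1] < self.speed_range[0]:
            raise ValueError("invalid speed range")
        if self.noise_jump_range[0] <= 2.5:
            raise ValueError("noise jumps must exceed the 2.5 m outlier threshold")

    @property
    def n_minutes(self) -> int:
        return int(round(self.days * 1440))

    @property
    def t0(self) -> pd.Timestamp:
        return pd.Timestamp(self.start, tz="UTC")

    @property
    def central_position(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)

    def bed_coords(self) -> np.ndarray:
        beds = default_bed_layout(self.width, self.height, self.n_beds)
        if ((beds[:, 0] < 0) | (beds[:, 0] > self.width) | (beds[:, 1] < 0) | (beds[:, 1] > self.height)).any():
            raise ValueError("bed coordinates outside the unit")
        return beds

    def shadow_params(self) -> ShadowParams:
        return ShadowParams(d_cells=self.d_cells, T_minutes=self.T_minutes)

    def build_grid(self) -> UnitGrid:
        return build_grid((self.width, self.height))

    def rngs(self) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
        """Independent substreams (trajectories, corruption, events)."""
        t, c, e = np.random.SeedSequence(self.seed).spawn(3)
        return (np.random.default_rng(t), np.random.default_rng(c), np.random.default_rng(e))


@dataclass
class SimTruth:
    """Pre-corruption ground truth, recorded for scoring QC and recovery."""

    shadow: ShadowSeries
    beta0_fall: float | None
    beta_shadow_fall: float
    beta0_icu: float | None
    beta_shadow_icu: float
    fall_minutes: np.ndarray
    icu_minutes: np.ndarray
    noise_keys: set
    missing_keys: set


@dataclass
class SimResult:
    config: SimConfig
    grid: UnitGrid
    clean_stream: PositionStream
    stream: PositionStream  # after corruption
    frames: MinuteFrames
    events: pd.DataFrame
    truth: SimTruth


def _empty_stream() -> PositionStream:
    df = pd.DataFrame(
        {
            "tag_id": pd.Series(dtype=str),
            "t": pd.Series(dtype="datetime64[ns, UTC]"),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
        }
    )
    return PositionStream(df=df)


def simulate_trajectories(
    config: SimConfig, rng: np.random.Generator | None = None
) -> PositionStream:
    """Simulate workstation emission streams over the configured span.

    Each workstation alternates bedside dwells (stationary 1/min beaconing)
    with straight-line transits at a speed drawn uniformly from
    ``speed_range`` (1 Hz beaconing).  The next stop is the central station
    with probability ``p_central``, otherwise preferentially a bed within
    ``move_locality_m`` of the current one — a rounding-style local walk.
    """
    if rng is None:
        rng = config.rngs()[0]
    if config.n_workstations == 0:
        return _empty_stream()
    beds = config.bed_coords()
    central = np.array(config.central_position)
    total = config.days * 86400.0
    dt_stat = config.emission_stationary_s
    dt_move = 1.0 / config.emission_moving_hz
    mu = math.log(config.dwell_median_minutes * 60.0)
    parts = []
    for w in range(config.n_workstations):
        tag = f"ws{w + 1:02d}"
        times: list[np.ndarray] = []
        xs: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        pos = beds[rng.integers(len(beds))].astype(float)
        t = 0.0
        while t < total:
            dwell = float(rng.lognormal(mu, config.dwell_sigma))
            beacon = t + dt_stat * np.arange(int(dwell // dt_stat) + 1)
            beacon = beacon[beacon < min(t + dwell, total)]
            times.append(beacon)
            xs.append(np.full(len(beacon), pos[0]))
            ys.append(np.full(len(beacon), pos[1]))
            t += dwell
            if t >= total:
                break
            # choose next stop
            if rng.random() < config.p_central and not np.allclose(pos, central):
                target = central.copy()
            else:
                d = np.linalg.norm(beds - pos, axis=1)
                local = np.flatnonzero((d > 1e-9) & (d <= config.move_locality_m))
                if len(local) > 0 and rng.random() < config.p_local:
                    target = beds[rng.choice(local)].astype(float)
                else:
                    faraway = np.flatnonzero(d > 1e-9)
                    if len(faraway) == 0:  # single-bed unit: stay put
                        continue
                    target = beds[rng.choice(faraway)].astype(float)
            speed = rng.uniform(*config.speed_range)
            duration = float(np.linalg.norm(target - pos)) / speed
            steps = t + dt_move * np.arange(1, int(duration // dt_move) + 1)
            steps = steps[steps < min(t + duration, total)]
            frac = (steps - t) / duration
            times.append(steps)
            xs.append(pos[0] + frac * (target[0] - pos[0]))
            ys.append(pos[1] + frac * (target[1] - pos[1]))
            t += duration
            pos = target
        tt = np.concatenate(times)
        parts.append(
            pd.DataFrame(
                {
                    "tag_id": tag,
                    "t": config.t0 + pd.to_timedelta(tt, unit="s"),
                    "x": np.concatenate(xs),
                    "y": np.concatenate(ys),
                }
            )
        )
    return PositionStream.from_dataframe(pd.concat(parts, ignore_index=True))


def _stream_keys(df: pd.DataFrame, idx: np.ndarray) -> set:
    return set(zip(df["tag_id"].iloc[idx], df["t"].iloc[idx]))


def corrupt(
    stream: PositionStream, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PositionStream, dict]:
    """Inject missing emissions and isolated positional jumps.

    Points are deleted independently with ``missing_prob``; of the survivors,
    interior points are displaced with ``noise_prob`` by a jump of magnitude
    drawn from ``noise_jump_range`` (well above the 2.5 m outlier rule) in a
    uniform direction.  Selected points are kept isolated — never adjacent to
    another displaced point — matching the artifact the noise filter targets.
    Returns the corrupted stream and a dict with ``noise_keys`` /
    ``missing_keys`` identifying injected artifacts by ``(tag_id, t)``.
    """
    if rng is None:
        rng = config.rngs()[1]
    df = stream.df.reset_index(drop=True)
    # deletion pass
    delete = rng.random(len(df)) < config.missing_prob
    missing_keys = _stream_keys(df, np.flatnonzero(delete))
    df = df[~delete].reset_index(drop=True)
    # isolated displacement pass
    noise_rows: list[int] = []
    for _, idx in df.groupby("tag_id", sort=False).indices.items():
        if len(idx) < 3:
            continue
        sel = np.flatnonzero(rng.random(len(idx)) < config.noise_prob)
        sel = sel[(sel > 0) & (sel < len(idx) - 1)]
        last = -2
        for s in sel:
            if s - last >= 2:  # keep displaced points isolated
                noise_rows.append(int(idx[s]))
                last = s
    noise_rows_arr = np.array(sorted(noise_rows), dtype=int)
    if len(noise_rows_arr):
        mag = rng.uniform(*config.noise_jump_range, size=len(noise_rows_arr))
        ang = rng.uniform(0, 2 * np.pi, size=len(noise_rows_arr))
        df.loc[noise_rows_arr, "x"] += mag * np.cos(ang)
        df.loc[noise_rows_arr, "y"] += mag * np.sin(ang)
    noise_keys = _stream_keys(df, noise_rows_arr)
    out = PositionStream(df=df, n_dropped=stream.n_dropped, n_duplicates=stream.n_duplicates)
    return out, {"noise_keys": noise_keys, "missing_keys": missing_keys}


def calibrate_intercept(
    percent: np.ndarray, beta: float, target_rate: float, lo: float = -40.0, hi: float = 10.0
) -> float:
    """Bisection for the intercept giving a target mean per-minute event rate.

    Solves ``mean(expit(b0 + beta * percent)) = target_rate`` for ``b0``; the
    mean probability is strictly increasing in the intercept, so bisection on
    a wide bracket converges unconditionally.
    """
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must be in (0, 1)")

    def mean_rate(b0: float) -> float:
        return float(expit(b0 + beta * percent).mean())

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_events(
    series: ShadowSeries,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    kind: str = "fall",
) -> tuple[pd.DataFrame, float]:
    """Draw per-minute Bernoulli events from a logistic model on shadow %.

    Fall odds increase with shadow (slope ln(1.02)/point by default), ICU
    odds decrease (ln(0.99)/point).  The intercept, unless set explicitly, is
    calibrated so the expected event count matches the study scale (8 falls /
    89 transfers per 210 days) times the configured inflation factor.
    Returns the event log and the intercept used.
    """
    if rng is None:
        rng = config.rngs()[2]
    if kind == "fall":
        beta = config.beta_shadow_fall
        b0 = config.beta0_fall
        rate = FALL_RATE_PER_MINUTE * config.fall_rate_inflation
        subtypes = FALLER_TYPES
    elif kind == "icu_transfer":
        beta = config.beta_shadow_icu
        b0 = config.beta0_icu
        rate = ICU_RATE_PER_MINUTE * config.icu_rate_inflation
        subtypes = ICU_CAUSES
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    if b0 is None:
        b0 = calibrate_intercept(series.percent, beta, rate)
    p = expit(b0 + beta * series.percent)
    if p.sum() < 1:
        warnings.warn(f"expected {kind} count {p.sum():.2f} < 1 over the simulated span")
    hit = rng.random(series.n_minutes) < p
    minutes = np.flatnonzero(hit)
    names = [s for s, _ in subtypes]
    probs = np.array([w for _, w in subtypes])
    labels = rng.choice(names, size=len(minutes), p=probs / probs.sum())
    events = pd.DataFrame(
        {
            "kind": kind,
            "t": series.t0 + pd.to_timedelta(minutes * 60 + 30, unit="s"),
            "subtype": labels,
            "minute": minutes,
        }
    )
    return events, b0


def _inject_bedside_clustering(
    stream: PositionStream,
    icu_minutes: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> PositionStream:
    """Replace one workstation's emissions before each transfer with bedside beacons.

    Emulates intensified bedside care: during the ``clustering_minutes``
    preceding each ICU transfer, a randomly chosen workstation is parked at a
    randomly chosen patient bed, beaconing at the stationary cadence.  The
    relocation is a sustained excursion, so it survives the isolated-outlier
    noise filter.
    """
    if len(icu_minutes) == 0:
        return stream
    beds = config.bed_coords()
    tags = stream.tags
    df = stream.df
    windows: dict[str, list[tuple[float, float, np.ndarray]]] = {t: [] for t in tags}
    for m in icu_minutes:
        tag = tags[rng.integers(len(tags))]
        bed = beds[rng.integers(len(beds))]
        start_s = max(0.0, (m - config.clustering_minutes) * 60.0)
        windows[tag].append((start_s, m * 60.0, bed))
    t0 = config.t0
    parts = [df]
    drop = np.zeros(len(df), dtype=bool)
    tsec = (df["t"] - t0).dt.total_seconds().to_numpy()
    for tag, wins in windows.items():
        if not wins:
            continue
        tag_mask = (df["tag_id"] == tag).to_numpy()
        for start_s, end_s, bed in wins:
            drop |= tag_mask & (tsec >= start_s) & (tsec < end_s)
            beacon = start_s + config.emission_stationary_s * np.arange(
                int((end_s - start_s) // config.emission_stationary_s) + 1
            )
            beacon = beacon[beacon < end_s]
            parts.append(
                pd.DataFrame(
                    {
                        "tag_id": tag,
                        "t": t0 + pd.to_timedelta(beacon, unit="s"),
                        "x": bed[0],
                        "y": bed[1],
                    }
                )
            )
    parts[0] = df[~drop]
    return PositionStream.from_dataframe(pd.concat(parts, ignore_index=True))


def simulate_study(config: SimConfig) -> SimResult:
    """Run the full generative model: trajectories → events → corruption.

    ICU transfers are drawn first (from the first-pass shadow series); when
    bedside clustering is enabled the trajectories are then amended and the
    shadow series recomputed, and falls are drawn from the final series, so
    the fall–shadow association reflects the coefficients exactly while the
    ICU association also carries the mechanistic bedside-care signal.
    """
    rng_traj, rng_corrupt, rng_events = config.rngs()
    grid = config.build_grid()
    params = config.shadow_params()
    clean = simulate_trajectories(config, rng_traj)
    if len(clean) == 0:
        frames = MinuteFrames(
            t0=config.t0,
            tags=[],
            x=np.empty((config.n_minutes, 0)),
            y=np.empty((config.n_minutes, 0)),
            staleness=np.empty((config.n_minutes, 0), dtype=np.int32),
        )
    else:
        frames = resample_per_minute(
            clean, grid, max_staleness=config.max_staleness, n_minutes=config.n_minutes, t0=config.t0
        )
    series = shadow_series(frames, grid, params)

    b0_icu = None
    if config.simulate_icu:
        icu_events, b0_icu = simulate_events(series, config, rng_events, kind="icu_transfer")
        if config.icu_clustering and len(icu_events):
            clean = _inject_bedside_clustering(
                clean, icu_events["minute"].to_numpy(), config, rng_events
            )
            frames = resample_per_minute(
                clean, grid, max_staleness=config.max_staleness, n_minutes=config.n_minutes, t0=config.t0
            )
            series = shadow_series(frames, grid, params)
    else:
        icu_events = pd.DataFrame({"kind": [], "t": [], "subtype": [], "minute": []})

    fall_events, b0_fall = simulate_events(series, config, rng_events, kind="fall")
    if len(icu_events):
        events = (
            pd.concat([fall_events, icu_events], ignore_index=True)
            .sort_values("t")
            .reset_index(drop=True)
        )
    else:
        events = fall_events.reset_index(drop=True)

    corrupted, artifacts = corrupt(clean, config, rng_corrupt)
    truth = SimTruth(
        shadow=series,
        beta0_fall=b0_fall,
        beta_shadow_fall=config.beta_shadow_fall,
        beta0_icu=b0_icu,
        beta_shadow_icu=config.beta_shadow_icu,
        fall_minutes=fall_events["minute"].to_numpy(),
        icu_minutes=icu_events["minute"].to_numpy() if len(icu_events) else np.array([], dtype=int),
        noise_keys=artifacts["noise_keys"],
        missing_keys=artifacts["missing_keys"],
    )
    return SimResult(
        config=config,
        grid=grid,
        clean_stream=clean,
        stream=corrupted,
        frames=frames,
        events=events,
        truth=truth,
    )


def score_noise_recovery(
    corrupted: PositionStream, filtered: PositionStream, noise_keys: set
) -> dict:
    """Sensitivity and false-positive rate of noise filtering vs injected truth."""
    kept = set(zip(filtered.df["tag_id"], filtered.df["t"]))
    all_keys = set(zip(corrupted.df["tag_id"], corrupted.df["t"]))
    flagged = all_keys - kept
    tp = len(flagged & noise_keys)
    fp = len(flagged - noise_keys)
    n_clean = len(all_keys) - len(noise_keys)
    return {
        "n_injected": len(noise_keys),
        "n_flagged": len(flagged),
        "sensitivity": tp / len(noise_keys) if noise_keys else float("nan"),
        "false_positive_rate": fp / n_clean if n_clean else float("nan"),
    }
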