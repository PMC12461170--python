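"""Linking clinical events to the shadow series and the statistical battery.

The unit of analysis is the minute.  Each analyzed minute carries the
percentage of spatial shadow zone, flags marking whether it falls in the
exposure window preceding (and including) a fall or ICU-transfer event, the
day of week, and the patient-to-nurse ratio of the shift containing it.  On
that table the module runs Welch two-sample t tests (event vs non-event
minutes), multivariable logistic regressions adjusted for day of week and
staffing ratio, a (dilation × persistence) sensitivity grid of
difference-in-means CIs, a temporal split-half analysis, and the standard
fall-rate-per-1000-patient-days computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .grid_coverage import MinuteFrames, UnitGrid
from .rtls_io import ShiftSchedule
from .shadow_zone import DEFAULT_D_LIST, DEFAULT_T_LIST, ShadowSeries, sensitivity_surface

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "SeparationError",
    "label_minutes",
    "compare_groups",
    "fit_fall_model",
    "fit_icu_model",
    "sensitivity_table",
    "split_half",
    "fall_rate",
]

DAY_ORDER = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")


class SeparationError(RuntimeError):
    """Raised when a logistic fit is perfectly (or quasi-)separated."""


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-sample comparison of shadow percentage between groups."""

    mean_event: float
    sd_event: float
    n_event: int
    mean_other: float
    sd_other: float
    n_other: int
    difference: float
    ci95: tuple[float, float]
    p_value: float

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0 or hi < 0

    def to_dict(self) -> dict:
        return {
            "mean_event": self.mean_event,
            "sd_event": self.sd_event,
            "n_event": self.n_event,
            "mean_other": self.mean_other,
            "sd_other": self.sd_other,
            "n_other": self.n_other,
            "difference": self.difference,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class RegressionResult:
    """Odds ratios with Wald 95% CIs from a multivariable logistic model."""

    table: pd.DataFrame  # index: predictor; columns: odds_ratio, ci_low, ci_high, p_value
    n: int
    outcome: str
    notes: tuple[str, ...] = ()

    def odds_ratio(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "odds_ratio"])

    def ci(self, predictor: str) -> tuple[float, float]:
        row = self.table.loc[predictor]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "p_value"])


def label_minutes(
    events: pd.DataFrame,
    series: ShadowSeries,
    schedule: ShiftSchedule | None = None,
    window_minutes: int | None = None,
    patients_only: bool = False,
) -> pd.DataFrame:
    """Build the minute-level analysis table from a shadow series and events.

    A minute is event-flagged iff it lies in the ``window_minutes`` window
    ending at (and including) the event's minute; overlapping windows merge
    and windows are clipped to the series span.  The default window equals
    the series' persistence threshold T, reflecting the exposure period over
    which the shadow statistic is defined.  ``patients_only`` restricts fall
    flags to events whose subtype is ``"patient"``.
    """
    schedule = schedule or ShiftSchedule.default()
    if window_minutes is None:
        window_minutes = series.params.T_minutes
    if window_minutes < 1:
        raise ValueError("window_minutes must be >= 1")
    n = series.n_minutes
    ts = series.timestamps()
    flags = {"fall": np.zeros(n, dtype=bool), "icu_transfer": np.zeros(n, dtype=bool)}
    for _, ev in events.iterrows():
        if patients_only and ev["kind"] == "fall" and ev.get("subtype", "patient") not in ("", "patient"):
            continue
        m = int((ev["t"] - series.t0) // pd.Timedelta(minutes=1))
        if not 0 <= m < n:
            warnings.warn(f"event at {ev['t']} outside series span; skipped")
            continue
        flags[ev["kind"]][max(0, m - window_minutes + 1) : m + 1] = True
    hours = ts.hour.to_numpy()
    ratios = schedule.ratios_by_hour()[hours]
    table = pd.DataFrame(
        {
            "minute": np.arange(n),
            "timestamp": ts,
            "percent_shadow": series.percent,
            "fall_flag": flags["fall"],
            "icu_flag": flags["icu_transfer"],
            "day_of_week": pd.Categorical(ts.day_name(), categories=list(DAY_ORDER)),
            "patient_to_nurse_ratio": ratios,
        }
    )
    return table[series.analyzed].reset_index(drop=True)


def compare_groups(table: pd.DataFrame, outcome: str = "fall_flag") -> ComparisonResult:
    """Welch independent-samples t test (2-tailed) of shadow % by event flag.

    The difference and its 95% CI are oriented event-minus-non-event, so a
    positive difference means more shadow around events.
    """
    flagged = table.loc[table[outcome], "percent_shadow"].to_numpy(float)
    other = table.loc[~table[outcome], "percent_shadow"].to_numpy(float)
    if len(flagged) < 2 or len(other) < 2:
        raise ValueError(f"each {outcome} group needs at least 2 minutes")
    res = stats.ttest_ind(flagged, other, equal_var=False)
    ci = res.confidence_interval(0.95)
    return ComparisonResult(
        mean_event=float(flagged.mean()),
        sd_event=float(flagged.std(ddof=1)),
        n_event=len(flagged),
        mean_other=float(other.mean()),
        sd_other=float(other.std(ddof=1)),
        n_other=len(other),
        difference=float(flagged.mean() - other.mean()),
        ci95=(float(ci.low), float(ci.high)),
        p_value=float(res.pvalue),
    )


def _fit_logit(table: pd.DataFrame, outcome: str) -> RegressionResult:
    y = table[outcome].astype(int)
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome} has a single class")
    for col in ("percent_shadow", "patient_to_nurse_ratio"):
        if table[col].nunique() < 2:
            raise ValueError(f"predictor {col} is constant")
    formula = (
        f"{outcome.replace('_flag', '_y')} ~ percent_shadow + patient_to_nurse_ratio"
        " + C(day_of_week, Treatment('Monday'))"
    )
    data = table.copy()
    data[outcome.replace("_flag", "_y")] = y
    notes: list[str] = []
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.filterwarnings("ignore", message="Maximum Likelihood optimization failed")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        singular = False
        try:
            fit = smf.logit(formula, data=data).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation fitting {outcome} model: {exc}") from exc
        except np.linalg.LinAlgError:
            singular = True  # singular Hessian: treat like non-convergence below
            fit = None
        if singular or not fit.mle_retvals.get("converged", True):
            # With rare outcomes, a weekday with zero events quasi-separates
            # its dummy (MLE at -inf) and stalls Newton even though every
            # other coefficient is identified.  BFGS converges with the
            # divergent dummy at a large finite value; the affected levels
            # are reported as non-estimable rather than failing the fit.
            by_day = data.groupby("day_of_week", observed=False)[
                outcome.replace("_flag", "_y")
            ].sum()
            zero_levels = [str(d) for d in by_day.index[by_day == 0]]
            if zero_levels:
                notes.append(
                    "zero-event day levels (dummy not estimable): " + ", ".join(zero_levels)
                )
                fit = smf.logit(formula, data=data).fit(disp=0, maxiter=500, method="bfgs")
            if fit is None or not fit.mle_retvals.get("converged", True):
                raise SeparationError(f"logistic fit for {outcome} did not converge")
    params = fit.params
    rows = {}
    with np.errstate(over="ignore"):
        conf = fit.conf_int()
        for name in params.index:
            if name == "Intercept":
                label = "intercept"
            elif name.startswith("C(day_of_week"):
                label = "day_" + name.split("[T.")[-1].rstrip("]")
            else:
                label = name
            rows[label] = {
                "odds_ratio": float(np.exp(params[name])),
                "ci_low": float(np.exp(conf.loc[name, 0])),
                "ci_high": float(np.exp(conf.loc[name, 1])),
                "p_value": float(fit.pvalues[name]),
                "coef": float(params[name]),
                "se": float(fit.bse[name]),
            }
    return RegressionResult(
        table=pd.DataFrame(rows).T, n=len(table), outcome=outcome, notes=tuple(notes)
    )


def fit_fall_model(table: pd.DataFrame) -> RegressionResult:
    """Logistic regression of per-minute fall exposure on shadow percentage.

    Adjusts for patient-to-nurse ratio and day of week (Monday reference);
    odds ratios are per percentage point of shadow, with Wald 95% CIs.
    """
    return _fit_logit(table, "fall_flag")


def fit_icu_model(table: pd.DataFrame) -> RegressionResult:
    """As :func:`fit_fall_model`, for the ICU-transfer outcome."""
    return _fit_logit(table, "icu_flag")


def sensitivity_table(
    frames: MinuteFrames,
    grid: UnitGrid,
    events: pd.DataFrame,
    schedule: ShiftSchedule | None = None,
    d_list: Sequence[int] = DEFAULT_D_LIST,
    T_list: Sequence[int] = DEFAULT_T_LIST,
    outcome: str = "fall_flag",
) -> pd.DataFrame:
    """Difference-in-means 95% CI for every (dilation, persistence) pair.

    For each (d, T) the shadow series is rebuilt, minutes relabelled with an
    exposure window equal to T, and the Welch comparison rerun; a pair whose
    groups are too small is reported as NA.
    """
    surface = sensitivity_surface(frames, grid, d_list=d_list, T_list=T_list)
    rows = []
    for (d, T), series in sorted(surface.items()):
        tbl = label_minutes(events, series, schedule=schedule, window_minutes=T)
        try:
            cmp = compare_groups(tbl, outcome)
            rows.append(
                {
                    "d_cells": d,
                    "T_minutes": T,
                    "difference": cmp.difference,
                    "ci_low": cmp.ci95[0],
                    "ci_high": cmp.ci95[1],
                    "p_value": cmp.p_value,
                    "significant": cmp.significant,
                }
            )
        except ValueError as exc:
            warnings.warn(f"(d={d}, T={T}): {exc}")
            rows.append(
                {
                    "d_cells": d,
                    "T_minutes": T,
                    "difference": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "significant": False,
                }
            )
    return pd.DataFrame(rows)


def split_half(
    table: pd.DataFrame, outcome: str = "fall_flag"
) -> tuple[ComparisonResult | None, ComparisonResult | None]:
    """Rerun the group comparison on the first and second half of the study.

    The split point is the midpoint week boundary (whole weeks counted from
    the table's first minute).  A half without both groups yields ``None``
    with a warning.
    """
    t_start = table["timestamp"].iloc[0]
    span = table["timestamp"].iloc[-1] - t_start
    n_weeks = int(np.ceil(span / pd.Timedelta(weeks=1)))
    if n_weeks < 2:
        raise ValueError("split-half analysis needs a span of at least 2 weeks")
    cut = t_start + pd.Timedelta(weeks=n_weeks // 2)
    halves = [table[table["timestamp"] < cut], table[table["timestamp"] >= cut]]
    out = []
    for i, half in enumerate(halves, start=1):
        try:
            out.append(compare_groups(half, outcome))
        except ValueError as exc:
            warnings.warn(f"half {i}: {exc}")
            out.append(None)
    return out[0], out[1]


def fall_rate(n_falls: int, n_beds: int, n_days: int) -> float:
    """Fall rate per 1000 patient-days, to one decimal.

    Patient-days are beds × days (full occupancy assumed, the convention
    when census data are unavailable).
    """
    if n_falls < 0 or n_beds < 0 or n_days < 0:
        raise ValueError("inputs must be nonnegative")
    if n_beds * n_days == 0:
        raise ValueError("beds × days must be positive")
    return round(1000.0 * n_falls / (n_beds * n_days), 1)
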