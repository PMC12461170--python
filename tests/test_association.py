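"""Minute labelling, group comparisons, logistic models and rates."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from shadowzone.association import (
    SeparationError,
    compare_groups,
    fall_rate,
    fit_fall_model,
    fit_icu_model,
    label_minutes,
    split_half,
)
from shadowzone.rtls_io import ShiftSchedule
from shadowzone.shadow_zone import ShadowParams, ShadowSeries

from conftest import T0

DAYS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")


def _series(percent, T=60):
    return ShadowSeries(
        percent=np.asarray(percent, float), params=ShadowParams(T_minutes=T), t0=T0
    )


def _events(minutes, kind="fall", subtype="patient"):
    return pd.DataFrame(
        {
            "kind": kind,
            "t": [T0 + pd.Timedelta(seconds=m * 60 + 30) for m in minutes],
            "subtype": subtype,
        }
    )


def _synthetic_table(rng, n, beta_shadow=0.0, beta_ratio=0.0, base_logit=-6.0, outcome="fall_flag"):
    """Minute table with Bernoulli outcomes from a known logistic model."""
    ts = T0 + pd.to_timedelta(np.arange(1, n + 1), unit="min")
    shadow = np.clip(rng.normal(75, 8, n), 0, 100)
    ratios = ShiftSchedule.default().ratios_by_hour()[ts.hour.to_numpy()]
    p = expit(base_logit + beta_shadow * shadow + beta_ratio * ratios)
    flags = rng.random(n) < p
    table = pd.DataFrame(
        {
            "minute": np.arange(n),
            "timestamp": ts,
            "percent_shadow": shadow,
            "fall_flag": False,
            "icu_flag": False,
            "day_of_week": pd.Categorical(ts.day_name(), categories=list(DAYS)),
            "patient_to_nurse_ratio": ratios,
        }
    )
    table[outcome] = flags
    return table


class TestLabelMinutes:
    def test_single_event_full_window(self):
        table = label_minutes(_events([200]), _series(np.zeros(500)), window_minutes=60)
        assert table["fall_flag"].sum() == 60
        flagged = table.loc[table["fall_flag"], "minute"]
        assert flagged.min() == 141 and flagged.max() == 200

    def test_overlapping_windows_merge(self):
        table = label_minutes(_events([100, 130]), _series(np.zeros(500)), window_minutes=60)
        # brute-force union of the two 60-minute windows
        expected = set()
        for m in (100, 130):
            expected |= set(range(m - 59, m + 1))
        assert table["fall_flag"].sum() == len(expected) == 90

    def test_left_truncated_window(self):
        table = label_minutes(_events([10]), _series(np.zeros(500)), window_minutes=60)
        assert table["fall_flag"].sum() == 11

    def test_event_outside_span_skipped(self):
        with pytest.warns(UserWarning, match="outside"):
            table = label_minutes(_events([999]), _series(np.zeros(500)), window_minutes=60)
        assert table["fall_flag"].sum() == 0

    def test_flag_count_bounded(self):
        rng = np.random.default_rng(30)
        minutes = rng.choice(np.arange(60, 1900), size=12, replace=False)
        table = label_minutes(_events(sorted(minutes)), _series(np.zeros(2000)), window_minutes=45)
        assert table["fall_flag"].sum() <= 12 * 45

    def test_patients_only_filter(self):
        ev = pd.concat([_events([100], subtype="patient"), _events([300], subtype="staff")])
        table = label_minutes(ev, _series(np.zeros(500)), window_minutes=60, patients_only=True)
        assert table["fall_flag"].sum() == 60

    def test_ratio_and_day_attached(self):
        table = label_minutes(_events([30]), _series(np.zeros(1440)), window_minutes=10)
        # series starts 2024-08-04 (a Sunday) at midnight: night shift, ratio 10
        assert table["patient_to_nurse_ratio"].iloc[0] == 10.0
        assert table["day_of_week"].iloc[0] == "Sunday"
        assert table["patient_to_nurse_ratio"].iloc[8 * 60] == 7.0


class TestCompareGroups:
    def test_identical_groups(self):
        values = np.tile([70.0, 75.0, 80.0], 4)
        table = pd.DataFrame(
            {"percent_shadow": values, "fall_flag": [True, False] * 6}
        )
        res = compare_groups(table)
        assert res.difference == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_recovers_study_scale_difference(self):
        # groups drawn with the observed summary statistics as truth:
        # fall minutes N(77.8, 10.9²) n=470 vs others N(76.8, 10.3²) n=249,893
        rng = np.random.default_rng(31)
        fall = rng.normal(77.8, 10.9, 470)
        other = rng.normal(76.8, 10.3, 249_893)
        table = pd.DataFrame(
            {
                "percent_shadow": np.r_[fall, other],
                "fall_flag": np.r_[np.ones(470, bool), np.zeros(249_893, bool)],
            }
        )
        res = compare_groups(table)
        se = np.sqrt(10.9**2 / 470 + 10.3**2 / 249_893)
        assert res.difference == pytest.approx(1.0, abs=3 * se)
        lo, hi = res.ci95
        assert lo <= res.difference <= hi

    def test_ci_coverage_of_known_shift(self):
        rng = np.random.default_rng(32)
        delta, hits = 2.0, 0
        for _ in range(200):
            a = rng.normal(70 + delta, 5, 60)
            b = rng.normal(70, 5, 400)
            table = pd.DataFrame(
                {
                    "percent_shadow": np.r_[a, b],
                    "fall_flag": np.r_[np.ones(60, bool), np.zeros(400, bool)],
                }
            )
            lo, hi = compare_groups(table).ci95
            hits += lo <= delta <= hi
        assert 0.90 <= hits / 200 <= 0.98

    def test_small_group_rejected(self):
        table = pd.DataFrame({"percent_shadow": [1.0, 2.0, 3.0], "fall_flag": [True, False, False]})
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups(table)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(33)
        table = _synthetic_table(rng, 2000, beta_shadow=0.02, base_logit=-4)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        assert compare_groups(table).difference == pytest.approx(
            compare_groups(shuffled).difference
        )


class TestLogisticModels:
    def test_recovers_fall_odds_ratio(self):
        rng = np.random.default_rng(34)
        table = _synthetic_table(rng, 60_000, beta_shadow=np.log(1.02), base_logit=-5.5)
        fit = fit_fall_model(table)
        lo, hi = fit.ci("percent_shadow")
        assert lo < 1.02 < hi
        assert fit.odds_ratio("percent_shadow") == pytest.approx(1.02, abs=0.02)

    def test_null_effect_gives_unit_odds_ratio(self):
        rng = np.random.default_rng(35)
        table = _synthetic_table(rng, 40_000, beta_shadow=0.0, base_logit=-4.0)
        fit = fit_fall_model(table)
        lo, hi = fit.ci("percent_shadow")
        assert lo < 1.0 < hi

    def test_recovers_staffing_ratio_effect(self):
        # ratio effect OR 0.84 per patient-per-nurse with null day effects
        rng = np.random.default_rng(36)
        table = _synthetic_table(
            rng, 60_000, beta_shadow=np.log(1.02), beta_ratio=np.log(0.84), base_logit=-3.5
        )
        fit = fit_fall_model(table)
        lo, hi = fit.ci("patient_to_nurse_ratio")
        assert lo < 0.84 < hi

    def test_recovers_inverse_icu_association(self):
        rng = np.random.default_rng(37)
        table = _synthetic_table(
            rng, 60_000, beta_shadow=np.log(0.99), base_logit=-2.5, outcome="icu_flag"
        )
        fit = fit_icu_model(table)
        lo, hi = fit.ci("percent_shadow")
        assert lo < 0.99 < hi
        assert fit.odds_ratio("percent_shadow") < 1.0

    def test_perfect_separation_diagnosed(self):
        rng = np.random.default_rng(38)
        table = _synthetic_table(rng, 400)
        table["fall_flag"] = table["percent_shadow"] > 75
        with pytest.raises((SeparationError, ValueError)):
            fit_fall_model(table)

    def test_zero_event_day_levels_tolerated(self):
        # a weekday with no events quasi-separates its dummy; the fit must
        # still converge and flag the level as non-estimable
        rng = np.random.default_rng(45)
        table = _synthetic_table(rng, 7 * 1440, beta_shadow=0.02, base_logit=-6.0)
        monday = table["day_of_week"] == "Tuesday"
        table.loc[monday, "fall_flag"] = False
        if table["fall_flag"].sum() < 5:  # ensure both classes remain
            table.loc[table.index[:5], "fall_flag"] = True
        fit = fit_fall_model(table)
        assert fit.odds_ratio("percent_shadow") > 0
        if any("Tuesday" in n for n in fit.notes):
            assert "zero-event" in fit.notes[0]

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(39)
        table = _synthetic_table(rng, 400)
        table["fall_flag"] = False
        with pytest.raises(ValueError, match="single class"):
            fit_fall_model(table)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(40)
        table = _synthetic_table(rng, 20_000, beta_shadow=0.02, base_logit=-4.5)
        shuffled = table.sample(frac=1, random_state=2).reset_index(drop=True)
        a = fit_fall_model(table).odds_ratio("percent_shadow")
        b = fit_fall_model(shuffled).odds_ratio("percent_shadow")
        assert a == pytest.approx(b, rel=1e-8)


class TestSplitHalf:
    def _table(self, rng, n_weeks=4, effect_half2_only=False):
        n = n_weeks * 7 * 1440
        table = _synthetic_table(rng, n, beta_shadow=0.0, base_logit=-5.2)
        if effect_half2_only:
            half2 = table.index >= n // 2
            boost = table["fall_flag"] & half2
            table.loc[boost, "percent_shadow"] += 10.0
        return table

    def test_halves_partition_and_pool(self):
        rng = np.random.default_rng(41)
        table = self._table(rng)
        h1, h2 = split_half(table)
        assert h1.n_event + h1.n_other + h2.n_event + h2.n_other == len(table)
        pooled = compare_groups(table)
        assert pooled.n_event == h1.n_event + h2.n_event

    def test_homogeneous_halves_compatible(self):
        rng = np.random.default_rng(42)
        h1, h2 = split_half(self._table(rng))
        # overlapping CIs for the same null effect
        assert h1.ci95[0] <= h2.ci95[1] and h2.ci95[0] <= h1.ci95[1]

    def test_effect_only_in_second_half(self):
        rng = np.random.default_rng(43)
        h1, h2 = split_half(self._table(rng, effect_half2_only=True))
        assert not h1.significant
        assert h2.significant

    def test_short_span_rejected(self):
        rng = np.random.default_rng(44)
        with pytest.raises(ValueError, match="2 weeks"):
            split_half(_synthetic_table(rng, 1440))


class TestFallRate:
    @pytest.mark.parametrize(
        "falls,beds,days,expected",
        [(8, 40, 210, 1.0), (0, 40, 210, 0.0), (1, 1, 1000, 1.0), (21, 40, 210, 2.5)],
    )
    def test_examples(self, falls, beds, days, expected):
        assert fall_rate(falls, beds, days) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            fall_rate(1, 0, 210)
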