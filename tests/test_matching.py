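"""Control-day eligibility, sampling, and the lagged analysis table."""

import numpy as np
import pandas as pd
import pytest

from heatmatch.matching import (
    MatchConfig,
    build_matched_table,
    eligible_controls,
    match_controls,
    sample_controls,
)

from conftest import make_calendar, random_multiyear_calendar


def brute_eligible(calendar, zcta, case_date, cfg):
    """Independent enumeration of eligible controls by literal rule-checking."""
    sub = calendar[calendar["zcta"] == zcta]
    case_date = pd.Timestamp(case_date)
    anchor_month = int(sub["date"].dt.month.min())

    def season_idx(d):
        return (d - pd.Timestamp(d.year, anchor_month, 1)).days

    hw_dates = set(sub.loc[sub["is_heatwave"], "date"])
    out = []
    for _, row in sub.iterrows():
        d = row["date"]
        if d.year == case_date.year:
            continue
        off = season_idx(d) - season_idx(case_date)
        if not (-cfg.window_before_days <= off <= cfg.window_after_days):
            continue
        if not row.get("scored", True):
            continue
        if row["is_heatwave"]:
            continue
        if any(
            abs((d - h).days) <= cfg.buffer_days for h in hw_dates
        ):
            continue
        out.append(d)
    return sorted(out)


class TestEligibility:
    def test_matches_brute_force_enumeration(self, rng):
        cfg = MatchConfig()
        for rep in range(25):
            cal = random_multiyear_calendar(np.random.default_rng(rep))
            cases = cal.loc[cal["is_heatwave"], "date"]
            if cases.empty:
                continue
            case = cases.iloc[len(cases) // 2]
            got = eligible_controls("Z0001", case, cal, cfg)
            assert sorted(got) == brute_eligible(cal, "Z0001", case, cfg)

    def test_heatwave_free_other_years_all_window_days_eligible(self):
        # heatwave only in 2011; 2012 and 2013 are clean in the window
        flags11 = np.zeros(60, bool)
        flags11[30] = True
        cal = pd.concat(
            [
                make_calendar(flags11, year=2011, start="2011-05-01"),
                make_calendar(np.zeros(60, bool), year=2012, start="2012-05-01"),
                make_calendar(np.zeros(60, bool), year=2013, start="2013-05-01"),
            ],
            ignore_index=True,
        )
        got = eligible_controls("Z0001", pd.Timestamp("2011-05-31"), cal)
        assert len(got) == 10 * 2  # (-2..+7) window in each of two clean years

    def test_single_year_calendar_has_no_controls(self):
        flags = np.zeros(60, bool)
        flags[30] = True
        cal = make_calendar(flags)
        assert eligible_controls("Z0001", pd.Timestamp("2011-05-31"), cal) == []

    def test_buffer_excludes_neighbors_of_other_events(self):
        # case year 2011; 2012 has a heatwave day; days within 3 days of it
        # are excluded even though they are themselves non-heatwave
        flags11 = np.zeros(60, bool)
        flags11[30] = True
        flags12 = np.zeros(60, bool)
        flags12[32] = True  # a different event in the control year
        cal = pd.concat(
            [
                make_calendar(flags11, year=2011, start="2011-05-01"),
                make_calendar(flags12, year=2012, start="2012-05-01"),
            ],
            ignore_index=True,
        )
        got = eligible_controls("Z0001", pd.Timestamp("2011-05-31"), cal)
        # window covers 2012 season-days 28..37; 29..35 lie in the buffer of
        # the 2012 heatwave on season-day 32 (2012-06-02)
        banned = {pd.Timestamp("2012-06-02") + pd.Timedelta(days=k) for k in range(-3, 4)}
        assert not banned & set(got)
        candidate_2_after = pd.Timestamp("2012-06-04")
        assert candidate_2_after not in got

    def test_unknown_zcta_raises(self):
        cal = make_calendar([False] * 10)
        with pytest.raises(KeyError):
            eligible_controls("Z9999", pd.Timestamp("2011-05-05"), cal)


class TestSampling:
    def test_exhaustive_when_pool_equals_n_controls(self):
        pool = [pd.Timestamp("2012-05-01") + pd.Timedelta(days=i) for i in range(3)]
        ms = sample_controls(("Z0001", "2011-05-10"), pool, MatchConfig(seed=0))
        assert set(ms.control_dates) == set(pool)

    def test_empty_pool_drops_case(self):
        assert sample_controls(("Z0001", "2011-05-10"), [], MatchConfig()) is None

    def test_uniform_selection_frequencies(self):
        pool = [pd.Timestamp("2012-05-01") + pd.Timedelta(days=i) for i in range(20)]
        rng = np.random.default_rng(42)
        hits = np.zeros(20)
        n_rep = 10_000
        cfg = MatchConfig()
        for _ in range(n_rep):
            ms = sample_controls(("Z0001", "2011-05-10"), pool, cfg, rng=rng)
            for d in ms.control_dates:
                hits[(d - pool[0]).days] += 1
        p = 3 / 20
        se = np.sqrt(p * (1 - p) / n_rep)
        np.testing.assert_allclose(hits / n_rep, p, atol=3 * se)

    def test_determinism_across_runs(self, rng):
        cal = random_multiyear_calendar(np.random.default_rng(5))
        s1, d1 = match_controls(cal, MatchConfig(seed=11))
        s2, d2 = match_controls(cal, MatchConfig(seed=11))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_controls_revalidate_and_no_leakage(self):
        cfg = MatchConfig()
        for rep in range(20):
            cal = random_multiyear_calendar(np.random.default_rng(1000 + rep))
            sets, _ = match_controls(cal, cfg)
            if sets.empty:
                continue
            hw_dates = set(cal.loc[cal["is_heatwave"], "date"])
            for set_id, g in sets.groupby("set_id"):
                case = g.loc[g["role"] == "case", "date"].iloc[0]
                ok = set(brute_eligible(cal, "Z0001", case, cfg))
                for c in g.loc[g["role"] == "control", "date"]:
                    assert c in ok
                    assert c not in hw_dates
                    assert all(
                        abs((c - h).days) > cfg.buffer_days for h in hw_dates
                    )

    def test_drop_report_records_unmatchable_cases(self):
        flags = np.zeros(40, bool)
        flags[20] = True
        cal = make_calendar(flags)  # single year: nothing eligible
        sets, drops = match_controls(cal, MatchConfig())
        assert sets.empty
        assert len(drops) == 1
        assert drops["n_eligible"].iloc[0] == 0


class TestMatchedTable:
    def _toy(self):
        # one 3-day event in 2011, clean 2012
        flags11 = np.zeros(60, bool)
        flags11[30:33] = True
        cal = pd.concat(
            [
                make_calendar(flags11, year=2011, start="2011-05-01"),
                make_calendar(np.zeros(60, bool), year=2012, start="2012-05-01"),
            ],
            ignore_index=True,
        )
        sets, _ = match_controls(cal, MatchConfig(seed=3))
        dates = pd.concat(
            [
                pd.Series(pd.date_range("2011-05-01", periods=60)),
                pd.Series(pd.date_range("2012-05-01", periods=60)),
            ]
        )
        cohort = pd.DataFrame(
            {
                "zcta": "Z0001",
                "date": dates,
                "condition": "ALL",
                "count": 1,
                "population": 10_000,
            }
        )
        return cal, sets, cohort

    def test_case_rows_have_lag0_set(self):
        cal, sets, cohort = self._toy()
        tbl = build_matched_table(sets, cohort, cal, lag_max=7)
        cases = tbl[tbl["role"] == "case"]
        assert (cases["hw_lag0"] == 1).all()

    def test_control_rows_have_clean_lags(self):
        cal, sets, cohort = self._toy()
        tbl = build_matched_table(sets, cohort, cal, lag_max=7)
        controls = tbl[tbl["role"] == "control"]
        # 2012 has no heatwaves at all: every lag indicator is zero
        lag_cols = [f"hw_lag{l}" for l in range(8)]
        assert (controls[lag_cols].to_numpy() == 0).all()

    def test_lag_matrix_matches_hand_enumeration(self):
        cal, sets, cohort = self._toy()
        tbl = build_matched_table(sets, cohort, cal, lag_max=7)
        # event spans season-days 30,31,32 (2011-05-31 .. 2011-06-02);
        # the case on day 32 sees heatwaves at lags 0,1,2 and none earlier
        row = tbl[(tbl["role"] == "case") & (tbl["date"] == "2011-06-02")].iloc[0]
        expected = {0: 1, 1: 1, 2: 1, 3: 0, 4: 0, 5: 0, 6: 0, 7: 0}
        for l, v in expected.items():
            assert row[f"hw_lag{l}"] == v

    def test_missing_counts_zero_filled(self):
        cal, sets, cohort = self._toy()
        sparse = cohort.iloc[:10]
        tbl = build_matched_table(sets, sparse, cal, lag_max=3)
        assert (tbl["count"] >= 0).all()
        assert tbl["population"].nunique() == 1

    def test_by_axis_expands_rows_per_level(self):
        cal, sets, cohort = self._toy()
        cohort = pd.concat(
            [cohort.assign(age_band="lt35"), cohort.assign(age_band="ge35")],
            ignore_index=True,
        )
        tbl = build_matched_table(sets, cohort, cal, lag_max=3, by="age_band")
        base = build_matched_table(sets, cohort, cal, lag_max=3)
        assert len(tbl) == 2 * len(base)
        merged = tbl.groupby(["set_id", "date"])["count"].sum()
        pd.testing.assert_series_equal(
            merged.sort_index(),
            base.set_index(["set_id", "date"])["count"].sort_index(),
            check_names=False,
        )
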