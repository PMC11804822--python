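"""Heatwave detection: thresholds, EHF scoring, intensity tiers, run finding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from heatmatch.exposure import (
    ExposureConfig,
    classify_intensity,
    compute_ehf,
    compute_t95,
    percentile_runs,
    segment_events,
)

from conftest import make_calendar, make_weather


def oracle_percentile(values, q):
    """Sort-and-linearly-interpolate percentile, written independently."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def oracle_ehf(temps, t95, mean_w=3, accl_w=30):
    """Literal per-day loop applying the three defining formulas (trailing)."""
    n = len(temps)
    out = []
    for i in range(n):
        if i - (mean_w - 1) - accl_w < 0:
            out.append((np.nan, np.nan, np.nan))
            continue
        m = sum(temps[i - mean_w + 1 : i + 1]) / mean_w
        accl = sum(temps[i - mean_w + 1 - accl_w : i - mean_w + 1]) / accl_w
        sig = m - t95
        out.append((sig, m - accl, sig * max(1.0, m - accl)))
    return out


class TestT95:
    def test_constant_series(self):
        w = make_weather(temps=np.full(120, 20.0))
        t95 = compute_t95(w, ExposureConfig())
        assert t95["Z0001"] == pytest.approx(20.0)

    def test_matches_sort_and_interpolate_oracle(self):
        temps = np.arange(1.0, 121.0)
        w = make_weather(temps=temps)
        t95 = compute_t95(w, ExposureConfig())
        assert t95["Z0001"] == pytest.approx(oracle_percentile(temps, 0.95), abs=1e-12)

    def test_translation_equivariance(self, rng):
        temps = rng.normal(25, 4, 150)
        w1 = make_weather(n_days=150, temps=temps)
        w2 = make_weather(n_days=150, temps=temps + 5.0, zcta="Z0002")
        both = pd.concat([w1, w2], ignore_index=True)
        t95 = compute_t95(both, ExposureConfig())
        assert t95["Z0002"] - t95["Z0001"] == pytest.approx(5.0, abs=1e-10)

    def test_too_few_days_names_the_zcta(self):
        w = make_weather(n_days=50)
        with pytest.raises(ValueError, match="Z0001"):
            compute_t95(w, ExposureConfig())


class TestEHF:
    def test_constant_series_has_no_heatwaves(self):
        cal = compute_ehf(make_weather(temps=np.full(120, 20.0)))
        scored = cal[cal["scored"]]
        assert (scored["ehi_sig"].abs() < 1e-12).all()
        assert (scored["ehf"].abs() < 1e-12).all()
        assert not cal["is_heatwave"].any()

    def test_matches_loop_oracle_on_random_series(self, rng):
        cfg = ExposureConfig()
        for _ in range(10):
            temps = rng.normal(25, 4, 120)
            w = make_weather(temps=temps)
            cal = compute_ehf(w, cfg).sort_values("date")
            t95 = oracle_percentile(temps, 0.95)
            expected = oracle_ehf(list(temps), t95)
            for row, (sig, accl, ehf) in zip(cal.itertuples(), expected):
                if np.isnan(ehf):
                    assert not row.scored
                else:
                    assert row.ehi_sig == pytest.approx(sig, abs=1e-9)
                    assert row.ehi_accl == pytest.approx(accl, abs=1e-9)
                    assert row.ehf == pytest.approx(ehf, abs=1e-9)

    def test_acclimatization_clamp(self):
        # 32 warm-up days at 20, then a mild bump: 0 < EHI_accl < 1 on a day
        # with EHI_sig > 0 leaves EHF = EHI_sig exactly
        temps = np.r_[np.full(40, 20.0), np.full(3, 20.5)]
        w = make_weather(n_days=43, temps=temps)
        cal = compute_ehf(w, ExposureConfig(min_days=40))
        last = cal.iloc[-1]
        assert 0 < last["ehi_accl"] < 1
        assert last["ehi_sig"] > 0
        assert last["ehf"] == pytest.approx(last["ehi_sig"], abs=1e-12)

    def test_heatwave_implies_positive_significance(self, rng):
        temps = rng.normal(25, 5, 153)
        cal = compute_ehf(make_weather(n_days=153, temps=temps))
        hw = cal[cal["is_heatwave"]]
        assert (hw["ehi_sig"] > 0).all()

    def test_warmup_days_unscored_per_season(self, rng):
        # 30 + 3 - 1 leading days of each season-year lack a full window
        frames = [
            make_weather(n_days=100, temps=rng.normal(25, 4, 100), year=y)
            for y in (2011, 2012)
        ]
        cal = compute_ehf(pd.concat(frames, ignore_index=True))
        for y in (2011, 2012):
            sub = cal[cal["date"].dt.year == y].sort_values("date")
            assert not sub["scored"].iloc[:32].any()
            assert sub["scored"].iloc[32:].all()

    def test_translation_leaves_heatwave_days_unchanged(self, rng):
        temps = rng.normal(25, 4, 153)
        c1 = compute_ehf(make_weather(n_days=153, temps=temps))
        c2 = compute_ehf(make_weather(n_days=153, temps=temps + 7.0))
        pd.testing.assert_series_equal(c1["is_heatwave"], c2["is_heatwave"])

    def test_gap_in_series_raises(self):
        w = make_weather(n_days=120)
        w = w.drop(index=60)
        with pytest.raises(ValueError, match="gaps"):
            compute_ehf(w)


class TestIntensity:
    @pytest.mark.parametrize(
        "ehf,expected",
        [
            (-1.0, "none"),
            (0.0, "none"),
            (0.5, "low"),
            (1.0, "moderate"),
            (1.5, "moderate"),
            (2.0, "high"),
            (3.0, "high"),
        ],
    )
    def test_boundary_grid(self, ehf, expected):
        assert classify_intensity(ehf) == expected

    def test_vectorized_matches_scalar(self):
        grid = np.array([-1.0, 0.0, 0.5, 1.0, 1.5, 2.0, 3.0])
        vec = classify_intensity(grid)
        assert list(vec) == [classify_intensity(x) for x in grid]


class TestPercentileRuns:
    def _weather_with_spikes(self, flags, base=20.0, spike=30.0):
        temps = np.where(np.asarray(flags, bool), spike, base)
        return make_weather(n_days=len(flags), temps=temps)

    def test_short_run_is_not_a_heatwave(self):
        flags = np.zeros(120, bool)
        flags[50:52] = True  # 2 consecutive exceedances < min_run_days
        cal = percentile_runs(
            self._weather_with_spikes(flags), ExposureConfig(definition="PCTL_TEMP")
        )
        assert not cal["is_heatwave"].any()

    def test_five_day_run_is_one_event(self):
        flags = np.zeros(120, bool)
        flags[50:55] = True
        cal = percentile_runs(
            self._weather_with_spikes(flags), ExposureConfig(definition="PCTL_TEMP")
        )
        assert int(cal["is_heatwave"].sum()) == 5
        assert cal.loc[cal["is_heatwave"], "event_id"].nunique() == 1

    def test_matches_scan_oracle(self, rng):
        cfg = ExposureConfig(definition="PCTL_TEMP")
        for _ in range(10):
            temps = rng.normal(25, 4, 120)
            w = make_weather(temps=temps)
            cal = percentile_runs(w, cfg).sort_values("date")
            thr = oracle_percentile(temps, 0.95)
            above = temps > thr
            expected = np.zeros(120, bool)
            i = 0
            while i < 120:
                j = i
                while j < 120 and above[j]:
                    j += 1
                if j - i >= 3:
                    expected[i:j] = True
                i = max(j, i + 1)
            assert (cal["is_heatwave"].to_numpy() == expected).all()


class TestSegmentEvents:
    def test_gap_splits_events(self):
        cal = make_calendar([True, True, False, True])
        ids = cal["event_id"].tolist()
        assert ids[0] == ids[1] == 1
        assert pd.isna(ids[2])
        assert ids[3] == 2

    def test_no_heatwaves_no_events(self):
        cal = make_calendar([False] * 5)
        assert cal["event_id"].isna().all()

    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_matches_brute_force_segmentation(self, flags):
        cal = make_calendar(flags)
        # brute force: new event whenever a heatwave day does not follow one
        expected = []
        eid = 0
        prev = False
        for f in flags:
            if f:
                if not prev:
                    eid += 1
                expected.append(eid)
            else:
                expected.append(None)
            prev = f
        got = [None if pd.isna(e) else int(e) for e in cal["event_id"]]
        assert got == expected

    def test_date_gap_splits_even_when_rows_adjacent(self):
        cal1 = make_calendar([True], start="2011-05-01")
        cal2 = make_calendar([True], start="2011-05-10")
        cal = segment_events(pd.concat([cal1, cal2], ignore_index=True))
        assert cal["event_id"].nunique() == 2
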