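"""Matched control-day sampling for heatwave days.

Each heatwave day (the *case*) is matched with up to ``n_controls`` randomly
selected non-heatwave days from the same ZCTA that fall within a seasonal
window of ``window_before_days`` days before to ``window_after_days`` days
after the case day — aligned across calendar years on a season-day index — in
a *different* year.  Candidate controls lying within ``buffer_days`` calendar
days of any heatwave day (default scope; configurable to days of events other
than the case's own) are excluded, as are days whose exposure could not be
scored (the acclimatization warm-up under the EHF definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "MatchConfig",
    "MatchedSet",
    "eligible_controls",
    "sample_controls",
    "match_controls",
    "build_matched_table",
]


@dataclass(frozen=True)
class MatchConfig:
    n_controls: int = 3
    window_before_days: int = 2
    window_after_days: int = 7
    buffer_days: int = 3
    min_controls: int = 1
    buffer_scope: str = "any"  # "any" | "other_event"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if self.buffer_days < 0:
            raise ValueError("buffer_days must be >= 0")
        if self.buffer_scope not in {"any", "other_event"}:
            raise ValueError("buffer_scope must be 'any' or 'other_event'")


@dataclass(frozen=True)
class MatchedSet:
    zcta: str
    case_date: pd.Timestamp
    control_dates: tuple[pd.Timestamp, ...]
    set_id: str


class _ZctaIndex:
    """Array view of one ZCTA's calendar for fast eligibility checks."""

    def __init__(self, sub: pd.DataFrame, config: MatchConfig):
        sub = sub.sort_values("date", kind="stable")
        self.dates = pd.to_datetime(sub["date"]).to_numpy()
        self.day_int = self.dates.astype("datetime64[D]").astype(np.int64)
        self.year = pd.DatetimeIndex(self.dates).year.to_numpy()
        # season-day index anchored at the first calendar month observed for
        # this unit: robust to leap years (no Feb 29 inside a warm season)
        months = pd.DatetimeIndex(self.dates).month
        anchor_month = int(months.min())
        anchors = pd.to_datetime(
            {"year": self.year, "month": anchor_month, "day": 1}
        ).to_numpy()
        self.season_idx = (
            (self.dates.astype("datetime64[D]") - anchors.astype("datetime64[D]"))
            .astype(np.int64)
        )
        self.is_hw = sub["is_heatwave"].to_numpy(dtype=bool)
        self.scored = (
            sub["scored"].to_numpy(dtype=bool)
            if "scored" in sub
            else np.ones(len(sub), dtype=bool)
        )
        self.event_id = (
            sub["event_id"].to_numpy(dtype=object)
            if "event_id" in sub
            else np.full(len(sub), None, dtype=object)
        )
        self.hw_days_sorted = np.sort(self.day_int[self.is_hw])
        b = config.buffer_days
        lo = np.searchsorted(self.hw_days_sorted, self.day_int - b, side="left")
        hi = np.searchsorted(self.hw_days_sorted, self.day_int + b, side="right")
        self.buffered_any = hi > lo
        if config.buffer_scope == "other_event":
            # per heatwave day remember its event, for scope filtering
            self.hw_events_sorted = np.asarray(
                [e for _, e in sorted(zip(self.day_int[self.is_hw], self.event_id[self.is_hw]))],
                dtype=object,
            )
        self.config = config

    def near_heatwave(self, day: int, exclude_event=None) -> bool:
        b = self.config.buffer_days
        lo = np.searchsorted(self.hw_days_sorted, day - b, side="left")
        hi = np.searchsorted(self.hw_days_sorted, day + b, side="right")
        if hi <= lo:
            return False
        if exclude_event is None:
            return True
        return any(e != exclude_event for e in self.hw_events_sorted[lo:hi])

    def eligible_mask(self, case_pos: int) -> np.ndarray:
        cfg = self.config
        case_year = self.year[case_pos]
        case_idx = self.season_idx[case_pos]
        mask = (
            self.scored
            & ~self.is_hw
            & (self.year != case_year)
            & (self.season_idx >= case_idx - cfg.window_before_days)
            & (self.season_idx <= case_idx + cfg.window_after_days)
        )
        if not mask.any():
            return mask
        if cfg.buffer_scope == "any":
            mask &= ~self.buffered_any
            return mask
        exclude_event = self.event_id[case_pos]
        for k in np.flatnonzero(mask):
            if self.near_heatwave(self.day_int[k], exclude_event):
                mask[k] = False
        return mask


def _zcta_index(calendar: pd.DataFrame, zcta: str, config: MatchConfig) -> _ZctaIndex:
    sub = calendar[calendar["zcta"] == zcta]
    if sub.empty:
        raise KeyError(f"ZCTA {zcta!r} not present in calendar")
    return _ZctaIndex(sub, config)


def eligible_controls(
    zcta: str,
    case_date,
    calendar: pd.DataFrame,
    config: MatchConfig | None = None,
) -> list[pd.Timestamp]:
    """All eligible control dates for one case day (see module docstring)."""
    config = config or MatchConfig()
    zi = _zcta_index(calendar, zcta, config)
    case_date = pd.Timestamp(case_date)
    pos = np.flatnonzero(zi.dates == case_date.to_datetime64())
    if len(pos) == 0:
        raise KeyError(f"case date {case_date.date()} not in calendar for {zcta}")
    mask = zi.eligible_mask(int(pos[0]))
    return [pd.Timestamp(d) for d in zi.dates[mask]]


def sample_controls(
    case: tuple[str, object],
    eligible: list,
    config: MatchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MatchedSet | None:
    """Sample min(n_controls, |eligible|) dates uniformly without replacement.

    Returns ``None`` when fewer than ``min_controls`` candidates exist (the
    case is dropped; callers record it in the drop report).
    """
    config = config or MatchConfig()
    if rng is None:
        rng = child_rng(config.seed, "matching")
    zcta, case_date = case
    case_date = pd.Timestamp(case_date)
    if len(eligible) < config.min_controls:
        return None
    k = min(config.n_controls, len(eligible))
    chosen = rng.choice(len(eligible), size=k, replace=False)
    dates = tuple(sorted(pd.Timestamp(eligible[int(i)]) for i in chosen))
    return MatchedSet(
        zcta=zcta,
        case_date=case_date,
        control_dates=dates,
        set_id=f"{zcta}:{case_date.date()}",
    )


def match_controls(
    calendar: pd.DataFrame, config: MatchConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match every heatwave day in *calendar* to sampled control days.

    Returns ``(sets, drops)``: *sets* is long-format with columns
    ``set_id, zcta, role ('case'|'control'), date``; *drops* lists case days
    that could not be matched, with the reason.
    """
    config = config or MatchConfig()
    rng = child_rng(config.seed, "matching")
    rows: list[tuple] = []
    drops: list[tuple] = []
    cal = calendar.sort_values(["zcta", "date"], kind="stable")
    for zcta, sub in cal.groupby("zcta", sort=True):
        zi = _ZctaIndex(sub, config)
        for pos in np.flatnonzero(zi.is_hw):
            case_date = pd.Timestamp(zi.dates[pos])
            mask = zi.eligible_mask(int(pos))
            eligible = zi.dates[mask]
            ms = sample_controls((zcta, case_date), list(eligible), config, rng)
            if ms is None:
                drops.append(
                    (zcta, case_date, len(eligible), "fewer than min_controls eligible")
                )
                continue
            rows.append((ms.set_id, zcta, "case", case_date))
            rows.extend((ms.set_id, zcta, "control", d) for d in ms.control_dates)
    sets = pd.DataFrame(rows, columns=["set_id", "zcta", "role", "date"])
    drop_report = pd.DataFrame(
        drops, columns=["zcta", "case_date", "n_eligible", "reason"]
    )
    return sets, drop_report


def build_matched_table(
    sets: pd.DataFrame,
    cohort: pd.DataFrame,
    calendar: pd.DataFrame,
    lag_max: int = 7,
    condition: str | None = None,
    by: str | None = None,
) -> pd.DataFrame:
    """One analysis row per matched-set member day (optionally per subgroup
    level of axis *by*): outcome count, population, calendar covariates, and
    heatwave indicators at lags 0..lag_max.

    ``hw_lag{l} = 1`` iff a heatwave occurred *l* days before the row's date
    in the row's ZCTA.  Lag look-backs that leave the observed calendar cause
    the row to be excluded (count available in ``.attrs['n_rows_dropped_lag']``).
    Counts absent from *cohort* are zero-filled.
    """
    if sets.empty:
        raise ValueError("no matched sets to build a table from")
    tbl = sets.copy()
    tbl["date"] = pd.to_datetime(tbl["date"])

    coh = cohort.copy()
    coh["date"] = pd.to_datetime(coh["date"])
    if condition is not None:
        coh = coh[coh["condition"] == condition]
    group_keys = ["zcta", "date"] + ([by] if by else [])
    agg = coh.groupby(group_keys, as_index=False, observed=True)["count"].sum()
    pop_map = coh.groupby("zcta")["population"].first()

    if by:
        levels = agg[by].unique()
        tbl = tbl.merge(pd.DataFrame({by: levels}), how="cross")
    tbl = tbl.merge(agg, on=group_keys, how="left")
    tbl["count"] = tbl["count"].fillna(0).astype(np.int64)
    tbl["population"] = tbl["zcta"].map(pop_map).astype(np.int64)
    tbl["dow"] = tbl["date"].dt.dayofweek
    tbl["year"] = tbl["date"].dt.year

    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    hw = cal.set_index(["zcta", "date"])["is_heatwave"]
    dropped = np.zeros(len(tbl), dtype=bool)
    for l in range(lag_max + 1):
        keys = pd.MultiIndex.from_arrays(
            [tbl["zcta"], tbl["date"] - pd.Timedelta(days=l)]
        )
        vals = hw.reindex(keys)
        missing = vals.isna().to_numpy()
        dropped |= missing
        tbl[f"hw_lag{l}"] = np.where(missing, False, vals.to_numpy(dtype=object) == True).astype(np.int8)
    n_drop = int(dropped.sum())
    if n_drop:
        tbl = tbl[~dropped].reset_index(drop=True)
    tbl.attrs["n_rows_dropped_lag"] = n_drop
    return tbl
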