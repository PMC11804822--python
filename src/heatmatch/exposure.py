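"""Heatwave detection per spatial unit (ZCTA).

Three definitions are supported:

``EHF``
    Excess Heat Factor.  For each day *i* let ``M(i)`` be the mean of
    ``mean_window_days`` (default 3) daily mean temperatures.  Then

    * ``EHI_sig(i)  = M(i) - T95``, the significance index, where ``T95`` is
      the unit's 95th-percentile daily mean temperature over the study period;
    * ``EHI_accl(i) = M(i) - mean of the accl_window_days (default 30) days
      immediately preceding the window``, the acclimatization index;
    * ``EHF(i) = EHI_sig(i) * max(1, EHI_accl(i))``  (units °C²).

    A day is a heatwave day iff ``EHF > 0``.  Intensity tiers: low
    ``0 < EHF < 1``, moderate ``1 <= EHF < 2``, high ``EHF >= 2``.

``PCTL_TEMP`` / ``PCTL_HI``
    Membership in a run of at least ``min_run_days`` (default 3) consecutive
    days strictly above the unit-specific percentile threshold of daily mean
    temperature / daily heat index.  No intensity tiers.

Daily series are scored within each (unit, season-year) block independently:
with warm-season-only data there is no cross-winter continuity, so the first
``accl_window_days + mean_window_days - 1`` days of each season cannot be
scored under the EHF definition and are flagged ``scored=False`` (never
heatwave days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExposureConfig",
    "compute_t95",
    "compute_ehf",
    "classify_intensity",
    "heat_index",
    "percentile_runs",
    "segment_events",
    "compute_calendar",
]

CALENDAR_COLUMNS = [
    "zcta",
    "date",
    "t95",
    "ehi_sig",
    "ehi_accl",
    "ehf",
    "scored",
    "is_heatwave",
    "intensity",
    "event_id",
]


@dataclass(frozen=True)
class ExposureConfig:
    """Settings for heatwave detection.

    Parameters
    ----------
    definition
        One of ``"EHF"``, ``"PCTL_TEMP"``, ``"PCTL_HI"``.
    percentile
        Threshold probability for T95 (default 0.95).
    accl_window_days
        Length of the acclimatization baseline (default 30 days).
    mean_window_days
        Length of the short-term mean window (default 3 days).
    min_run_days
        Minimum run length for the percentile definitions (default 3).
    window_alignment
        ``"trailing"`` (default): M(i) averages day i and the two prior days,
        so exposure is fully known on the day itself.  ``"leading"``: M(i)
        averages day i and the two following days (the original EHF
        convention).
    percentile_method
        Interpolation rule passed to :func:`numpy.quantile` (default
        ``"linear"``: linear interpolation between order statistics).
    min_days
        Minimum observed days per unit required to estimate T95.
    """

    definition: str = "EHF"
    percentile: float = 0.95
    accl_window_days: int = 30
    mean_window_days: int = 3
    min_run_days: int = 3
    window_alignment: str = "trailing"
    percentile_method: str = "linear"
    min_days: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must be in (0, 1)")
        if self.accl_window_days < self.mean_window_days:
            raise ValueError("accl_window_days must be >= mean_window_days")
        if self.min_run_days < 1:
            raise ValueError("min_run_days must be >= 1")
        if self.definition not in {"EHF", "PCTL_TEMP", "PCTL_HI"}:
            raise ValueError(f"unknown definition {self.definition!r}")
        if self.window_alignment not in {"trailing", "leading"}:
            raise ValueError("window_alignment must be 'trailing' or 'leading'")


def _as_datetime(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s)


def compute_t95(
    weather: pd.DataFrame, config: ExposureConfig, value_col: str = "tmean_c"
) -> pd.Series:
    """Per-unit percentile threshold of the daily series over all study days.

    Returns a Series indexed by ``zcta``.  Raises if any unit has fewer than
    ``config.min_days`` observed days.
    """
    counts = weather.groupby("zcta")[value_col].count()
    short = counts[counts < config.min_days]
    if len(short):
        raise ValueError(
            "too few observed days to estimate the percentile threshold for "
            f"ZCTA(s): {', '.join(map(str, short.index.tolist()))}"
        )
    return weather.groupby("zcta")[value_col].quantile(
        config.percentile, interpolation=config.percentile_method
    )


def _season_blocks(weather: pd.DataFrame) -> pd.DataFrame:
    """Sort and verify daily contiguity within (zcta, year) blocks."""
    w = weather.copy()
    w["date"] = _as_datetime(w["date"])
    w = w.sort_values(["zcta", "date"], kind="stable").reset_index(drop=True)
    dup = w.duplicated(["zcta", "date"])
    if dup.any():
        raise ValueError("duplicate (zcta, date) rows in weather table")
    w["season_year"] = w["date"].dt.year
    days = w["date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    codes = pd.MultiIndex.from_frame(w[["zcta", "season_year"]]).factorize()[0]
    step = np.diff(days)
    same = np.diff(codes) == 0
    bad = np.flatnonzero(same & (step != 1))
    if len(bad):
        gaps = []
        for k in bad[:20]:
            z = w["zcta"].iat[k]
            missing = pd.date_range(
                w["date"].iat[k] + pd.Timedelta(days=1),
                w["date"].iat[k + 1] - pd.Timedelta(days=1),
                freq="D",
            ).strftime("%Y-%m-%d")
            gaps.append(f"{z}: {', '.join(missing[:10])}")
        raise ValueError("gaps in daily series: " + "; ".join(gaps))
    return w


def _rolling_mean(x: np.ndarray, a_off: int, b_off: int) -> np.ndarray:
    """Mean of x[i+a_off .. i+b_off] inclusive; NaN where out of range."""
    n = len(x)
    width = b_off - a_off + 1
    cs = np.concatenate([[0.0], np.cumsum(x)])
    out = np.full(n, np.nan)
    i = np.arange(n)
    lo = i + a_off
    hi = i + b_off + 1  # exclusive
    ok = (lo >= 0) & (hi <= n)
    out[ok] = (cs[hi[ok]] - cs[lo[ok]]) / width
    return out


def compute_ehf(weather: pd.DataFrame, config: ExposureConfig | None = None) -> pd.DataFrame:
    """Score every day with EHI_sig, EHI_accl and EHF; flag heatwave days.

    The returned calendar has one row per (zcta, date) with columns
    ``t95, ehi_sig, ehi_accl, ehf, scored, is_heatwave, intensity, event_id``.
    Days without a full acclimatization history in their season-year block are
    ``scored=False`` with NaN indices and are never heatwave days.
    """
    config = config or ExposureConfig()
    w = _season_blocks(weather)
    t95 = compute_t95(w, config)
    m, a = config.mean_window_days, config.accl_window_days

    n = len(w)
    temps = w["tmean_c"].to_numpy(dtype=float)
    thr = w["zcta"].map(t95).to_numpy(dtype=float)
    mm = np.full(n, np.nan)
    ac = np.full(n, np.nan)
    for lo, hi in _group_slices(w, ["zcta", "season_year"]):
        t = temps[lo:hi]
        if config.window_alignment == "trailing":
            mm[lo:hi] = _rolling_mean(t, -(m - 1), 0)
            ac[lo:hi] = _rolling_mean(t, -(m - 1) - a, -m)
        else:  # leading
            mm[lo:hi] = _rolling_mean(t, 0, m - 1)
            ac[lo:hi] = _rolling_mean(t, -a, -1)

    sig = mm - thr
    accl = mm - ac  # short-term mean minus the acclimatization baseline
    with np.errstate(invalid="ignore"):
        ehf = sig * np.maximum(1.0, accl)
    scored = ~np.isnan(ehf)
    cal = w[["zcta", "date"]].copy()
    cal["t95"] = thr
    cal["ehi_sig"] = sig
    cal["ehi_accl"] = accl
    cal["ehf"] = ehf
    cal["scored"] = scored
    cal["is_heatwave"] = scored & np.where(np.isnan(ehf), False, ehf > 0)
    cal["intensity"] = classify_intensity(ehf)
    cal.loc[~cal["is_heatwave"], "intensity"] = "none"
    return segment_events(cal)


def _group_slices(df: pd.DataFrame, keys: list[str]):
    """Start/stop offsets of contiguous key groups in an already-sorted frame."""
    codes = pd.MultiIndex.from_frame(df[keys]).factorize()[0] if len(keys) > 1 else None
    if codes is None:
        codes = pd.factorize(df[keys[0]])[0]
    change = np.flatnonzero(np.diff(codes) != 0) + 1
    bounds = np.concatenate([[0], change, [len(df)]])
    return zip(bounds[:-1], bounds[1:])


def classify_intensity(ehf):
    """Map EHF (°C²) to an intensity tier.

    ``ehf <= 0`` → none; ``(0, 1)`` → low; ``[1, 2)`` → moderate;
    ``[2, ∞)`` → high.  The boundary at 2 is closed on the high side so the
    tiers partition the positive axis.  Accepts scalars or arrays; NaN → none.
    """
    x = np.asarray(ehf, dtype=float)
    out = np.full(x.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        out[(x > 0) & (x < 1)] = "low"
        out[(x >= 1) & (x < 2)] = "moderate"
        out[x >= 2] = "high"
    if np.isscalar(ehf) or x.ndim == 0:
        return str(out.item() if x.ndim == 0 else out)
    return out


def heat_index(tmean_c, rh_pct):
    """US National Weather Service heat index, computed in °F, returned in °C.

    Uses the Rothfusz (1990) regression with the published low-humidity
    (RH < 13 %, 80–112 °F) and high-humidity (RH > 85 %, 80–87 °F)
    adjustments, and the simple Steadman-average formula when that average is
    below 80 °F.  Conversions use exactly 9/5.  Accepts scalars or arrays.
    """
    t_c = np.asarray(tmean_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    t = t_c * 9.0 / 5.0 + 32.0

    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)
    hi = (simple + t) / 2.0  # Steadman average used for the branch decision

    full = (
        -42.379
        + 2.04901523 * t
        + 10.14333127 * rh
        - 0.22475541 * t * rh
        - 6.83783e-3 * t**2
        - 5.481717e-2 * rh**2
        + 1.22874e-3 * t**2 * rh
        + 8.5282e-4 * t * rh**2
        - 1.99e-6 * t**2 * rh**2
    )
    adj_low = ((13.0 - rh) / 4.0) * np.sqrt(
        np.clip(17.0 - np.abs(t - 95.0), 0.0, None) / 17.0
    )
    full = np.where((rh < 13.0) & (t >= 80.0) & (t <= 112.0), full - adj_low, full)
    adj_high = ((rh - 85.0) / 10.0) * ((87.0 - t) / 5.0)
    full = np.where((rh > 85.0) & (t >= 80.0) & (t <= 87.0), full + adj_high, full)

    out_f = np.where(hi >= 80.0, full, hi)
    out_c = (out_f - 32.0) * 5.0 / 9.0
    if np.isscalar(tmean_c) and np.isscalar(rh_pct):
        return float(out_c)
    return out_c


def percentile_runs(weather: pd.DataFrame, config: ExposureConfig) -> pd.DataFrame:
    """Heatwave calendar under a consecutive-exceedance percentile definition.

    Heatwave days are members of maximal runs of at least ``min_run_days``
    consecutive days strictly above the unit's percentile threshold of the
    metric (daily mean temperature for ``PCTL_TEMP``, daily heat index for
    ``PCTL_HI``).  Intensity is not defined for these definitions.
    """
    if config.definition not in {"PCTL_TEMP", "PCTL_HI"}:
        raise ValueError("percentile_runs requires a PCTL_* definition")
    w = _season_blocks(weather)
    if config.definition == "PCTL_HI":
        w = w.assign(metric=heat_index(w["tmean_c"].to_numpy(), w["rh_pct"].to_numpy()))
    else:
        w = w.assign(metric=w["tmean_c"])
    thr = compute_t95(w, config, value_col="metric")

    parts = []
    for (z, _), g in w.groupby(["zcta", "season_year"], sort=False):
        x = g["metric"].to_numpy(dtype=float)
        above = x > thr[z]
        hw = _runs_at_least(above, config.min_run_days)
        part = g[["zcta", "date"]].copy()
        part["t95"] = thr[z]
        part["ehi_sig"] = np.nan
        part["ehi_accl"] = np.nan
        part["ehf"] = np.nan
        part["scored"] = True
        part["is_heatwave"] = hw
        parts.append(part)
    cal = pd.concat(parts, ignore_index=True)
    cal["intensity"] = "none"
    return segment_events(cal)


def _runs_at_least(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Keep only True-runs of length >= min_len."""
    out = np.zeros_like(mask)
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def segment_events(calendar: pd.DataFrame) -> pd.DataFrame:
    """Assign an ``event_id`` to each maximal consecutive run of heatwave days.

    Ids are integers starting at 1 within each ZCTA; non-heatwave days get
    a missing id.  Calendar-date adjacency (not row adjacency) defines runs.
    """
    cal = calendar.copy()
    cal["date"] = _as_datetime(cal["date"])
    cal = cal.sort_values(["zcta", "date"], kind="stable").reset_index(drop=True)
    hw = cal["is_heatwave"].to_numpy(dtype=bool)
    days = cal["date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    zcode = pd.factorize(cal["zcta"])[0]
    prev_adjacent = np.concatenate(
        [[False], (zcode[1:] == zcode[:-1]) & (np.diff(days) == 1)]
    )
    prev_hw = np.concatenate([[False], hw[:-1]])
    start = hw & ~(prev_adjacent & prev_hw)
    cum = np.cumsum(start)
    zcta_first = np.concatenate([[True], zcode[1:] != zcode[:-1]])
    base_per_zcta = np.concatenate([[0], cum])[np.flatnonzero(zcta_first)]
    eid = cum - base_per_zcta[zcode]
    cal["event_id"] = pd.array(np.where(hw, eid, -1), dtype="Int64")
    cal.loc[~hw, "event_id"] = pd.NA
    return cal


def compute_calendar(weather: pd.DataFrame, config: ExposureConfig | None = None) -> pd.DataFrame:
    """Dispatch to :func:`compute_ehf` or :func:`percentile_runs` per config."""
    config = config or ExposureConfig()
    if config.definition == "EHF":
        return compute_ehf(weather, config)
    return percentile_runs(weather, config)
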