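"""Synthetic weather, ZCTA attributes, and daily ED-visit counts.

The generator emulates the structure of a warm-season (May–September)
multi-year ZCTA-level study: per-unit daily mean temperature built from a
seasonal sinusoid, AR(1) noise and injected multi-day heat episodes; bounded
AR(1) relative humidity; and daily outcome counts whose log-rate matches the
downstream model exactly,

    log mu = log(population) + log(baseline rate) + dow effect + year effect
             + sum_l  beta_l * HW(t - l),

so the distributed-lag relative risks injected here are the ground truth the
pipeline is expected to recover.  Overdispersion (phi > 1) is realized by
gamma-mixing (a negative-binomial mechanism with mean mu and variance
phi * mu), since quasi-Poisson fixes only the mean-variance relation.

Subgroup axes (age band, race, ethnicity, insurance) are generated
independently of each other with configurable mixing proportions; counts are
emitted at the cross-classified cell level so any single axis can be
marginalized for stratified analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "SyntheticConfig",
    "generate_weather",
    "generate_counts",
    "make_zcta_attributes",
]

logger = logging.getLogger(__name__)

# Mixing proportions follow the marginal composition of a large southeastern
# US maternal ED sample (unknown categories folded into the nearest bucket).
DEFAULT_SUBGROUP_MIX: dict[str, dict[str, float]] = {
    "age_band": {"lt35": 0.916, "ge35": 0.084},
    "race": {"White": 0.421, "Black": 0.444, "Other": 0.135},
    "ethnicity": {"NonHispanic": 0.907, "Hispanic": 0.093},
    "insurance": {"Medicaid": 0.553, "Private": 0.228, "SelfPay": 0.171, "Other": 0.048},
}


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for the synthetic study.

    Weather: ``tmean_c = baseline_temp_c + seasonal_amplitude_c *
    sin(pi * d / (L-1)) + AR(1) noise + episode_bump_c on episode days``,
    where d is the day-of-season and L the season length.  Episodes per
    (ZCTA, season) are Poisson(``episode_rate``) with lengths uniform over
    ``episode_len_days``.

    Counts: see module docstring.  ``true_log_rr_by_lag`` maps lag (0..7) to
    the injected log relative risk; ``effect_modifiers`` optionally overrides
    that map for cells of one subgroup level, e.g.
    ``{"age_band": {"ge35": {0: 0.1}}}``.
    """

    n_zcta: int = 30
    years: tuple[int, ...] = (2011, 2012, 2013)
    season_months: tuple[int, ...] = (5, 6, 7, 8, 9)
    baseline_temp_c: float = 24.0
    seasonal_amplitude_c: float = 5.0
    ar1_rho: float = 0.7
    noise_sd_c: float = 1.8
    episode_rate: float = 2.0
    episode_bump_c: float = 6.0
    episode_len_days: tuple[int, int] = (3, 6)
    pop_range: tuple[int, int] = (10_000, 50_000)
    true_log_rr_by_lag: dict[int, float] = field(default_factory=dict)
    baseline_rate_per_100k: float = 1.0
    dow_effects: tuple[float, ...] = (0.0, -0.02, -0.03, -0.02, 0.0, 0.05, 0.08)
    year_effects: dict[int, float] = field(default_factory=dict)
    subgroup_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBGROUP_MIX.items()}
    )
    effect_modifiers: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)
    dispersion: float = 1.0
    conditions: tuple[str, ...] = ("ALL",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zcta < 1:
            raise ValueError("n_zcta must be >= 1")
        if len(set(self.years)) != len(self.years):
            raise ValueError("years must be distinct")
        months = sorted(self.season_months)
        if months != list(range(months[0], months[-1] + 1)):
            raise ValueError("season_months must be consecutive calendar months")
        if self.episode_bump_c <= 0:
            raise ValueError("episode_bump_c must be > 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        for axis, mix in self.subgroup_mix.items():
            tot = sum(mix.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"subgroup_mix[{axis!r}] sums to {tot}, not 1")

    @property
    def zcta_ids(self) -> list[str]:
        return [f"Z{i:04d}" for i in range(1, self.n_zcta + 1)]

    def season_dates(self, year: int) -> pd.DatetimeIndex:
        months = sorted(self.season_months)
        start = pd.Timestamp(year, months[0], 1)
        end = pd.Timestamp(year, months[-1], 1) + pd.offsets.MonthEnd(0)
        return pd.date_range(start, end, freq="D")


def generate_weather(
    config: SyntheticConfig, return_episodes: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ZCTA daily mean temperature and relative humidity series.

    Returns a frame with columns ``zcta, date, tmean_c, rh_pct`` (and, when
    ``return_episodes`` is set, also the boolean injected-episode mask as an
    extra frame column ``episode``).
    """
    rng = child_rng(config.seed, "weather")
    zctas = config.zcta_ids
    frames = []
    for year in config.years:
        dates = config.season_dates(year)
        L = len(dates)
        d = np.arange(L)
        seasonal = config.baseline_temp_c + config.seasonal_amplitude_c * np.sin(
            np.pi * d / (L - 1)
        )
        for z in zctas:
            noise = _ar1(rng, L, config.ar1_rho, config.noise_sd_c)
            episode = np.zeros(L, dtype=bool)
            n_epi = rng.poisson(config.episode_rate)
            lo, hi = config.episode_len_days
            for _ in range(n_epi):
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, L))
                episode[start : start + length] = True
            t = seasonal + noise + np.where(episode, config.episode_bump_c, 0.0)
            rh = np.clip(65.0 + _ar1(rng, L, 0.5, 10.0), 20.0, 100.0)
            frames.append(
                pd.DataFrame(
                    {
                        "zcta": z,
                        "date": dates,
                        "tmean_c": t,
                        "rh_pct": rh,
                        "episode": episode,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["zcta", "date"], kind="stable").reset_index(drop=True)
    if not return_episodes:
        out = out.drop(columns="episode")
    return out


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) with marginal standard deviation *sd*."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = rng.normal(0.0, 1.0, n) * innov_sd
    e[0] = rng.normal(0.0, sd)  # stationary start
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -rho], e)


def make_zcta_attributes(config: SyntheticConfig) -> pd.DataFrame:
    """ZCTA attribute table: population, RUCA code, region, and ACS-style
    counts sufficient to compute the race and income concentration indices.

    Race counts are persons (advantaged = non-Hispanic White, disadvantaged =
    Black); income counts are households (advantaged = top-quintile income,
    disadvantaged = bottom-quintile income).
    """
    rng = child_rng(config.seed, "attributes")
    n = config.n_zcta
    pop = rng.integers(config.pop_range[0], config.pop_range[1] + 1, n)
    ruca = rng.integers(1, 11, n)
    region = rng.choice(["Western", "Piedmont", "Coastal"], n, p=[0.2, 0.5, 0.3])

    p_white = rng.beta(2.0, 2.0, n)
    p_black = (1.0 - p_white) * rng.beta(3.0, 1.5, n)
    households = np.maximum(1, (pop * rng.uniform(0.3, 0.45, n)).astype(np.int64))
    p_top = rng.beta(2.0, 6.0, n)
    p_bottom = np.minimum(rng.beta(2.0, 6.0, n), 1.0 - p_top)
    return pd.DataFrame(
        {
            "zcta": config.zcta_ids,
            "population": pop,
            "ruca_code": ruca,
            "region": region,
            "ice_race_advantaged": np.round(pop * p_white).astype(np.int64),
            "ice_race_disadvantaged": np.round(pop * p_black).astype(np.int64),
            "ice_race_total": pop,
            "ice_income_advantaged": np.round(households * p_top).astype(np.int64),
            "ice_income_disadvantaged": np.round(households * p_bottom).astype(np.int64),
            "ice_income_total": households,
        }
    )


def _cells(config: SyntheticConfig):
    """Cross-classified subgroup cells with (labels, proportion, lag map)."""
    axes = list(config.subgroup_mix)
    levels = [list(config.subgroup_mix[a].items()) for a in axes]
    for combo in product(*levels):
        labels = {a: lab for a, (lab, _) in zip(axes, combo)}
        prop = float(np.prod([p for (_, p) in combo]))
        lag_map = dict(config.true_log_rr_by_lag)
        for axis, overrides in config.effect_modifiers.items():
            if labels.get(axis) in overrides:
                lag_map = dict(overrides[labels[axis]])
        yield labels, prop, lag_map


def generate_counts(
    config: SyntheticConfig,
    calendar: pd.DataFrame,
    weather: pd.DataFrame,
    attributes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Daily outcome counts per (zcta, date, condition, subgroup cell).

    Counts are Poisson (or gamma-mixed Poisson when ``dispersion > 1``) with
    the log-rate described in the module docstring; heatwave lag indicators
    are read from *calendar*.  Days whose lag window reaches before the start
    of their season block are dropped with a logged warning (only possible
    when a nonzero-lag effect is configured).  Returns ``(counts, truth)``
    where *truth* records every injected parameter.
    """
    if attributes is None:
        attributes = make_zcta_attributes(config)
    rng = child_rng(config.seed, "counts")

    cal = calendar.sort_values(["zcta", "date"], kind="stable").reset_index(drop=True)
    cal["date"] = pd.to_datetime(cal["date"])
    dates = cal["date"]
    hw = cal["is_heatwave"].to_numpy(dtype=bool)
    season_year = dates.dt.year.to_numpy()
    zcode, _ = pd.factorize(cal["zcta"])

    max_lag = max([l for l, b in config.true_log_rr_by_lag.items() if b != 0.0], default=0)
    for overrides in config.effect_modifiers.values():
        for lag_map in overrides.values():
            nz = [l for l, b in lag_map.items() if b != 0.0]
            max_lag = max([max_lag, *nz]) if nz else max_lag

    # lag indicator matrix over the calendar; within-block shifts only
    block = pd.MultiIndex.from_arrays([zcode, season_year]).factorize()[0]
    n = len(cal)
    lag_ind = np.zeros((8, n), dtype=bool)
    lag_ind[0] = hw
    for l in range(1, 8):
        shifted = np.concatenate([np.zeros(l, dtype=bool), hw[:-l]])
        same = np.concatenate([np.zeros(l, dtype=bool), block[:-l] == block[l:]])
        lag_ind[l] = shifted & same

    # drop early-season days whose nonzero-lag window is unobservable
    keep = np.ones(n, dtype=bool)
    if max_lag > 0:
        first = np.concatenate([[True], block[1:] != block[:-1]])
        pos_in_block = np.arange(n) - np.maximum.accumulate(np.where(first, np.arange(n), 0))
        keep = pos_in_block >= max_lag
        if (~keep).any():
            logger.warning(
                "dropped %d early-season days whose lag-%d window precedes the series",
                int((~keep).sum()),
                max_lag,
            )

    pop = cal["zcta"].map(attributes.set_index("zcta")["population"]).to_numpy(dtype=float)
    dow = dates.dt.dayofweek.to_numpy()
    dow_eff = np.asarray(config.dow_effects)[dow]
    year_eff = np.array([config.year_effects.get(int(y), 0.0) for y in season_year])
    base_log_mu = (
        np.log(pop / 1e5)
        + np.log(config.baseline_rate_per_100k)
        + dow_eff
        + year_eff
    )

    frames = []
    phi = config.dispersion
    for condition in config.conditions:
        for labels, prop, lag_map in _cells(config):
            lag_term = np.zeros(n)
            for l, beta in lag_map.items():
                if beta != 0.0:
                    lag_term += beta * lag_ind[l]
            mu = np.exp(base_log_mu + np.log(prop) + lag_term)[keep]
            if phi > 1.0:
                lam = rng.gamma(mu / (phi - 1.0), phi - 1.0)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mu)
            df = pd.DataFrame(
                {
                    "zcta": cal["zcta"].to_numpy()[keep],
                    "date": dates.to_numpy()[keep],
                    "condition": condition,
                    "count": counts,
                    "population": pop[keep].astype(np.int64),
                }
            )
            for axis, lab in labels.items():
                df[axis] = lab
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    truth = {
        "seed": config.seed,
        "true_log_rr_by_lag": dict(config.true_log_rr_by_lag),
        "effect_modifiers": {
            a: {lab: dict(m) for lab, m in o.items()}
            for a, o in config.effect_modifiers.items()
        },
        "baseline_rate_per_100k": config.baseline_rate_per_100k,
        "dispersion": config.dispersion,
        "dow_effects": list(config.dow_effects),
        "year_effects": dict(config.year_effects),
        "n_days_dropped_for_lag": int((~keep).sum()),
    }
    return out, truth
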