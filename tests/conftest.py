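import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("heatmatch").setLevel(logging.ERROR)


def make_weather(
    n_days: int = 120,
    zcta: str = "Z0001",
    year: int = 2011,
    temps=None,
    rh: float = 65.0,
) -> pd.DataFrame:
    """A contiguous single-season daily weather frame starting May 1."""
    dates = pd.date_range(f"{year}-05-01", periods=n_days, freq="D")
    if temps is None:
        temps = np.full(n_days, 20.0)
    return pd.DataFrame(
        {"zcta": zcta, "date": dates, "tmean_c": np.asarray(temps, float), "rh_pct": rh}
    )


def make_calendar(
    hw_flags,
    zcta: str = "Z0001",
    year: int = 2011,
    start: str | None = None,
    scored=None,
) -> pd.DataFrame:
    """A hand-built heatwave calendar from a boolean flag sequence."""
    from heatmatch.exposure import segment_events

    n = len(hw_flags)
    dates = pd.date_range(start or f"{year}-05-01", periods=n, freq="D")
    cal = pd.DataFrame(
        {
            "zcta": zcta,
            "date": dates,
            "t95": 25.0,
            "ehi_sig": np.nan,
            "ehi_accl": np.nan,
            "ehf": np.nan,
            "scored": True if scored is None else np.asarray(scored, bool),
            "is_heatwave": np.asarray(hw_flags, dtype=bool),
        }
    )
    cal["intensity"] = np.where(cal["is_heatwave"], "low", "none")
    return segment_events(cal)


def random_multiyear_calendar(rng, zcta="Z0001", years=(2011, 2012, 2013), n_days=60, p_hw=0.08):
    """Random multi-year calendar with clustered heatwave days."""
    frames = []
    for y in years:
        flags = rng.random(n_days) < p_hw
        # encourage short runs so events exist
        flags |= np.roll(flags, 1) & (rng.random(n_days) < 0.5)
        frames.append(make_calendar(flags, zcta=zcta, year=y, start=f"{y}-05-01"))
    cal = pd.concat(frames, ignore_index=True)
    from heatmatch.exposure import segment_events

    return segment_events(cal)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
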