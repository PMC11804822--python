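"""Summary-table descriptives: level counts, percentages, chi-square tests.

Two denominator rules are explicit because published summary tables mix
them: ``all_visits`` divides by the total including unknown/missing labels
(used e.g. for ethnicity percentages), while ``known_only`` divides by the
sum over known labels and drops unknown rows (used e.g. for rural-urban class
and region, where unknown units are not tabulated).  Percentages are rounded
half-up to one decimal, matching the usual printed style.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "round_half_up",
    "summarize",
    "chi_square_gof",
    "load_table1",
    "compare_to_overall",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize(
    records: pd.DataFrame,
    axis: str | None = None,
    denominator_rule: str = "all_visits",
    unknown_labels: tuple[str, ...] = ("Unknown",),
    level_col: str = "level",
    n_col: str = "n",
) -> pd.DataFrame:
    """Counts and percentages per level of one categorical axis.

    *records* is either a visit-level frame (one row per visit; *axis* names
    the category column) or a pre-aggregated count table with columns
    ``level`` and ``n`` (optionally filtered by *axis* when an ``axis``
    column is present).
    """
    if records.empty:
        raise ValueError("empty input")
    if n_col in records.columns:
        df = records
        if axis is not None and "axis" in df.columns:
            df = df[df["axis"] == axis]
        counts = df.groupby(level_col, sort=False)[n_col].sum()
    else:
        if axis is None or axis not in records.columns:
            raise KeyError("visit-level input requires an existing axis column")
        counts = records[axis].value_counts(sort=False)
    if counts.empty:
        raise ValueError(f"no rows for axis {axis!r}")

    if denominator_rule == "all_visits":
        denom = int(counts.sum())
        out = counts
    elif denominator_rule == "known_only":
        out = counts[~counts.index.isin(unknown_labels)]
        denom = int(out.sum())
    else:
        raise ValueError("denominator_rule must be 'all_visits' or 'known_only'")
    if denom == 0:
        raise ValueError("zero denominator")
    res = out.rename("n").reset_index().rename(columns={out.index.name or "index": "level"})
    res["pct"] = [round_half_up(100.0 * n / denom) for n in res["n"]]
    res["denominator"] = denom
    res["denominator_rule"] = denominator_rule
    if axis is not None:
        res.insert(0, "axis", axis)
    return res


def chi_square_gof(observed, expected_props) -> tuple[float, float]:
    """Pearson goodness-of-fit: X² = Σ (O - E)² / E against expected
    proportions, df = k - 1."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    exp = obs.sum() * props
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be positive")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=len(obs) - 1))
    return stat, p


def load_table1() -> pd.DataFrame:
    """Packaged transcription of the published visit-summary counts
    (long format: axis, level, condition, n).

    Cells that could not be verified against row/column totals in the source
    are omitted; a few printed totals are internally inconsistent (see the
    methods note) and are transcribed as printed.
    """
    with resources.files("heatmatch.data").joinpath("table1_counts.csv").open() as fh:
        return pd.read_csv(fh)


def compare_to_overall(
    table1: pd.DataFrame, axis: str, condition: str, unknown_labels: tuple[str, ...] = ()
) -> tuple[float, float]:
    """Chi-square test of one outcome's level distribution against the
    all-visit proportions on the same axis (goodness-of-fit reading of a
    summary-table comparison)."""
    base = table1[(table1["axis"] == axis) & (table1["condition"] == "ALL")]
    out = table1[(table1["axis"] == axis) & (table1["condition"] == condition)]
    base = base[~base["level"].isin(unknown_labels)].set_index("level")["n"]
    out = out[~out["level"].isin(unknown_labels)].set_index("level")["n"]
    levels = [l for l in base.index if l in out.index]
    props = (base[levels] / base[levels].sum()).to_numpy()
    return chi_square_gof(out[levels].to_numpy(), props)
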