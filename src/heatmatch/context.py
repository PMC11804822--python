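"""Neighborhood-context indices: concentration at the extremes (ICE),
quintile assignment, and RUCA rural/suburban/urban classes.

ICE = (advantaged - disadvantaged) / total, in [-1, 1]: negative values mark
a concentration of the disadvantaged group (e.g. Black residents for the
racialized index, bottom-quintile-income households for the economic index),
positive values a concentration of the advantaged group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["ice", "assign_quintiles", "ruca_class", "ice_table", "RUCA_MAPPINGS"]

# "paper" follows the printed study mapping; "usda" is the conventional
# metropolitan-core reading of the same codes (1-3 metropolitan/urban).
RUCA_MAPPINGS = {
    "paper": {**{c: "Rural" for c in (1, 2, 3)},
              **{c: "Suburban" for c in (4, 5, 6)},
              **{c: "Urban" for c in (7, 8, 9, 10)}},
    "usda": {**{c: "Urban" for c in (1, 2, 3)},
             **{c: "Suburban" for c in (4, 5, 6)},
             **{c: "Rural" for c in (7, 8, 9, 10)}},
}


def ice(A, P, T):
    """Index of Concentration at the Extremes: (A - P) / T.

    A = advantaged count, P = disadvantaged count, T = total; requires T > 0
    and A + P <= T.  Accepts scalars or arrays.
    """
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("total count must be positive")
    if np.any(A + P > T + 1e-9):
        raise ValueError("advantaged + disadvantaged exceeds total")
    out = (A - P) / T
    return float(out) if out.ndim == 0 else out


def assign_quintiles(scores, invert: bool = False) -> np.ndarray:
    """Rank-based quintiles 1..5; Q1 holds the lowest scores.

    Cut rule: with minimum-rank ties (r = 1-based rank, 'min' method over n
    units), quintile = ceil(5 r / n).  Tied scores share a quintile; if all
    scores are equal every unit lands in Q1 (with a warning).  The rule
    depends on ranks only, so it is invariant to monotone transformations.
    ``invert=True`` flips the direction (Q1 = highest scores).
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 5:
        raise ValueError("at least 5 units are required for quintiles")
    if s.isna().any():
        raise ValueError("scores must not contain missing values")
    if s.nunique() == 1:
        warnings.warn("all scores identical; every unit assigned Q1", stacklevel=2)
    vals = -s if invert else s
    r = vals.rank(method="min").to_numpy()
    q = np.ceil(5.0 * r / len(s)).astype(np.int64)
    return np.clip(q, 1, 5)


def ruca_class(code: int, mapping: str = "paper") -> str:
    """Collapse a RUCA code (1-10) to Rural / Suburban / Urban."""
    try:
        table = RUCA_MAPPINGS[mapping]
    except KeyError:
        raise ValueError(f"unknown RUCA mapping {mapping!r}") from None
    code = int(code)
    if code not in table:
        raise ValueError(f"RUCA code must be in 1..10, got {code}")
    return table[code]


def ice_table(
    attributes: pd.DataFrame,
    race_cols: tuple[str, str, str] = (
        "ice_race_advantaged",
        "ice_race_disadvantaged",
        "ice_race_total",
    ),
    income_cols: tuple[str, str, str] = (
        "ice_income_advantaged",
        "ice_income_disadvantaged",
        "ice_income_total",
    ),
    invert_quintiles: bool = False,
) -> pd.DataFrame:
    """Per-ZCTA ICE race and income scores with quintile labels.

    Column mappings are configurable; defaults follow the package's attribute
    schema (race: non-Hispanic White vs Black persons; income: top- vs
    bottom-quintile-income households).
    """
    out = attributes[["zcta"]].copy()
    out["ice_race"] = ice(*(attributes[c] for c in race_cols))
    out["ice_income"] = ice(*(attributes[c] for c in income_cols))
    out["ice_race_q"] = assign_quintiles(out["ice_race"], invert=invert_quintiles)
    out["ice_income_q"] = assign_quintiles(out["ice_income"], invert=invert_quintiles)
    return out
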