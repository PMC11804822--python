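"""Subgroup-stratified fits and the Wald heterogeneity (effect-modification)
test.

For two subgroup estimates (beta1, SE1) and (beta2, SE2) on the log-RR scale,

    W = (beta1 - beta2)^2 / (SE1^2 + SE2^2)

is compared against a chi-squared distribution with one degree of freedom;
small upper-tail probabilities indicate effect modification.  For axes with
more than two levels each level is compared against a declared reference
level (or, optionally, all pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model import LagSpec, ModelFit, cumulative_rr, fit_conditional_quasipoisson

__all__ = [
    "StratumComparison",
    "stratified_fits",
    "effect_modification",
    "se_from_ci",
    "effect_modification_table",
]

Z975 = 1.959963984540054


@dataclass(frozen=True)
class StratumComparison:
    axis: str
    group1: str
    group2: str
    beta1: float
    beta2: float
    se1: float
    se2: float
    w: float
    p_em: float

    @property
    def significant(self) -> bool:
        return self.p_em < 0.05


def stratified_fits(
    table: pd.DataFrame,
    axis: str,
    lags: tuple[int, ...] = (0, 1, 2, 3),
    covariates: tuple[str, ...] = ("dow", "year"),
    strata: str = "zcta",
) -> tuple[dict[str, ModelFit], dict[str, str]]:
    """One independent model fit per level of *axis*.

    The table must carry the axis column (build it with
    ``build_matched_table(..., by=axis)``).  Returns ``(fits, unfit)`` where
    *unfit* maps levels that failed the fitting preconditions to the reason —
    failures are reported, never silently skipped.
    """
    if axis not in table:
        raise KeyError(f"axis column {axis!r} not in table")
    fits: dict[str, ModelFit] = {}
    unfit: dict[str, str] = {}
    for level, sub in table.groupby(axis, sort=True, observed=True):
        try:
            fits[str(level)] = fit_conditional_quasipoisson(
                sub.reset_index(drop=True),
                lags=lags,
                covariates=covariates,
                strata=strata,
            )
        except (ValueError, KeyError) as err:
            unfit[str(level)] = str(err)
    return fits, unfit


def effect_modification(
    beta1: float, se1: float, beta2: float, se2: float, axis: str = "", group1: str = "", group2: str = ""
) -> StratumComparison:
    """Wald heterogeneity test between two log-RR estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    w = (beta1 - beta2) ** 2 / (se1**2 + se2**2)
    p = float(stats.chi2.sf(w, df=1)) if w > 0 else 1.0
    return StratumComparison(
        axis=axis,
        group1=group1,
        group2=group2,
        beta1=float(beta1),
        beta2=float(beta2),
        se1=float(se1),
        se2=float(se2),
        w=float(w),
        p_em=p,
    )


def se_from_ci(rr: float, ci_low: float, ci_high: float) -> float:
    """Back out the log-RR standard error from a published RR and 95 % CI:
    ``se = (ln ci_high - ln ci_low) / (2 * 1.96)``.

    Lets published RR/CI pairs feed the heterogeneity test directly.
    """
    if not (0 < ci_low < rr < ci_high):
        raise ValueError("require 0 < ci_low < rr < ci_high")
    return float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z975))


def effect_modification_table(
    fits: dict[str, ModelFit],
    spec: LagSpec,
    axis: str,
    reference: str | None = None,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Heterogeneity tests across the levels of one stratification axis.

    Each level's cumulative (or single-lag) estimate is compared to the
    *reference* level's; with ``all_pairs`` every unordered pair is tested.
    Returns one row per comparison with the W statistic and chi²(1) p-value.
    """
    summaries = {
        lev: cumulative_rr(f, spec).iloc[0] for lev, f in fits.items()
    }
    rows = []
    if all_pairs:
        pairs = list(combinations(sorted(summaries), 2))
    else:
        if reference is None:
            raise ValueError("reference level required unless all_pairs=True")
        if reference not in summaries:
            raise KeyError(f"reference level {reference!r} has no fit")
        pairs = [(lev, reference) for lev in sorted(summaries) if lev != reference]
    for g1, g2 in pairs:
        s1, s2 = summaries[g1], summaries[g2]
        cmp_ = effect_modification(
            s1["beta"], s1["se"], s2["beta"], s2["se"], axis=axis, group1=g1, group2=g2
        )
        rows.append(
            {
                "axis": axis,
                "group1": g1,
                "group2": g2,
                "beta1": cmp_.beta1,
                "beta2": cmp_.beta2,
                "se1": cmp_.se1,
                "se2": cmp_.se2,
                "w": cmp_.w,
                "p_em": cmp_.p_em,
            }
        )
    return pd.DataFrame(rows)
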