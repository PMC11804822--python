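"""End-to-end orchestration: generate → exposure → match → fit → stratify →
describe, with every intermediate written to CSV and a JSON manifest
(seeds, file hashes, row and drop counts) sufficient to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import child_seed
from .context import ice_table
from .describe import summarize
from .exposure import ExposureConfig, compute_calendar
from .matching import MatchConfig, build_matched_table, match_controls
from .model import LagSpec, cumulative_rr, fit_conditional_quasipoisson
from .stratify import effect_modification_table, stratified_fits
from .synthetic import SyntheticConfig, generate_counts, generate_weather, make_zcta_attributes

__all__ = ["RunConfig", "run_pipeline", "export_forest_data"]

LAG_SPECS = {"acute": LagSpec.acute(), "prolonged": LagSpec.prolonged()}


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    The global *seed* fans out deterministically to the synthetic-data and
    matching stages (each stage keyed by name), so per-stage seeds need not
    be managed by hand.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    lag_specs: tuple[str, ...] = ("acute", "prolonged")
    axes: tuple[str, ...] = ()
    references: dict[str, str] = field(default_factory=dict)
    condition: str = "ALL"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.lag_specs:
            if name not in LAG_SPECS:
                raise ValueError(f"unknown lag spec {name!r}")
        self.synthetic = dataclasses.replace(
            self.synthetic, seed=child_seed(self.seed, "synthetic")
        )
        self.match = dataclasses.replace(self.match, seed=child_seed(self.seed, "matching"))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        if "synthetic" in kw:
            syn = dict(kw["synthetic"])
            for tup_key in ("years", "season_months", "episode_len_days", "pop_range",
                            "dow_effects", "conditions"):
                if tup_key in syn and isinstance(syn[tup_key], list):
                    syn[tup_key] = tuple(syn[tup_key])
            if "true_log_rr_by_lag" in syn:
                syn["true_log_rr_by_lag"] = {
                    int(k): float(v) for k, v in syn["true_log_rr_by_lag"].items()
                }
            kw["synthetic"] = SyntheticConfig(**syn)
        if "exposure" in kw:
            kw["exposure"] = ExposureConfig(**kw["exposure"])
        if "match" in kw:
            kw["match"] = MatchConfig(**kw["match"])
        for tup_key in ("lag_specs", "axes"):
            if tup_key in kw and isinstance(kw[tup_key], list):
                kw[tup_key] = tuple(kw[tup_key])
        return cls(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["files"][path.name] = {"sha256": _sha256(path), "n_rows": int(len(df))}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages, write every intermediate artifact under *outdir*,
    and return (and write) the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "synthetic": config.synthetic.seed,
            "matching": config.match.seed,
        },
        "files": {},
        "drops": {},
    }

    weather = generate_weather(config.synthetic)
    _write(weather, out / "weather.csv", manifest)

    attributes = make_zcta_attributes(config.synthetic)
    _write(attributes, out / "zcta_attributes.csv", manifest)
    _write(ice_table(attributes), out / "ice.csv", manifest)

    calendar = compute_calendar(weather, config.exposure)
    _write(calendar, out / "heatwave_calendar.csv", manifest)
    manifest["n_heatwave_days"] = int(calendar["is_heatwave"].sum())

    counts, truth = generate_counts(config.synthetic, calendar, weather, attributes)
    _write(counts, out / "counts.csv", manifest)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str))
    manifest["drops"]["early_season_days"] = truth["n_days_dropped_for_lag"]

    sets, drop_report = match_controls(calendar, config.match)
    _write(sets, out / "matched_sets.csv", manifest)
    _write(drop_report, out / "match_drops.csv", manifest)
    manifest["drops"]["unmatched_cases"] = int(len(drop_report))
    if sets.empty:
        raise RuntimeError("matching produced no sets; increase episode_rate or zctas")

    table = build_matched_table(sets, counts, calendar, lag_max=7, condition=config.condition)
    _write(table, out / "analysis_table.csv", manifest)
    manifest["drops"]["lag_window_rows"] = table.attrs.get("n_rows_dropped_lag", 0)

    results = []
    for spec_name in config.lag_specs:
        spec = LAG_SPECS[spec_name]
        fit = fit_conditional_quasipoisson(table, lags=spec.lags)
        row = cumulative_rr(fit, spec).iloc[0]
        results.append(
            {
                "axis": "pooled",
                "level": "pooled",
                "lagspec": spec_name,
                **{k: row[k] for k in ("rr", "ci_low", "ci_high", "p", "beta", "se")},
                "p_em": np.nan,
                "dispersion": fit.dispersion,
                "n_strata": fit.n_strata,
            }
        )

    for axis in config.axes:
        atable = build_matched_table(
            sets, counts, calendar, lag_max=7, condition=config.condition, by=axis
        )
        for spec_name in config.lag_specs:
            spec = LAG_SPECS[spec_name]
            fits, unfit = stratified_fits(atable, axis, lags=spec.lags)
            manifest["drops"].setdefault("unfit_subgroups", {}).update(
                {f"{axis}:{k}:{spec_name}": v for k, v in unfit.items()}
            )
            ref = config.references.get(axis)
            em = (
                effect_modification_table(fits, spec, axis, reference=ref)
                if ref and ref in fits
                else pd.DataFrame()
            )
            for level, f in fits.items():
                row = cumulative_rr(f, spec).iloc[0]
                p_em = np.nan
                if not em.empty:
                    hit = em[em["group1"] == level]
                    if len(hit):
                        p_em = float(hit["p_em"].iloc[0])
                results.append(
                    {
                        "axis": axis,
                        "level": level,
                        "lagspec": spec_name,
                        **{k: row[k] for k in ("rr", "ci_low", "ci_high", "p", "beta", "se")},
                        "p_em": p_em,
                        "dispersion": f.dispersion,
                        "n_strata": f.n_strata,
                    }
                )

    results_df = pd.DataFrame(results)
    _write(results_df, out / "results.csv", manifest)

    desc = pd.concat(
        [
            summarize(counts.rename(columns={ax: "level"}), axis=ax,
                      level_col="level", n_col="count")
            for ax in ("age_band", "race", "ethnicity", "insurance")
            if ax in counts.columns
        ],
        ignore_index=True,
    )
    _write(desc, out / "descriptives.csv", manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def export_forest_data(
    results: pd.DataFrame, path: str | Path, plot: bool = False
) -> pd.DataFrame:
    """Write tidy forest-plot data (one row per axis/level/lagspec) and
    optionally an unstyled errorbar plot next to it."""
    cols = [c for c in ("axis", "level", "lagspec", "rr", "ci_low", "ci_high", "p", "p_em")
            if c in results.columns]
    tidy = results[cols].copy()
    path = Path(path)
    tidy.to_csv(path, index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(tidy))))
        ypos = np.arange(len(tidy))[::-1]
        ax.errorbar(
            tidy["rr"],
            ypos,
            xerr=[tidy["rr"] - tidy["ci_low"], tidy["ci_high"] - tidy["rr"]],
            fmt="o",
            capsize=2,
        )
        ax.axvline(1.0, color="grey", lw=0.8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(tidy["axis"] + "/" + tidy["level"] + " (" + tidy["lagspec"] + ")")
        ax.set_xlabel("relative risk")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return tidy
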