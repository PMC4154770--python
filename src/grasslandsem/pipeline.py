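"""Study orchestration: per region and year, metrics → moments → SEM fits →
pruning/fallback → standardized total effects, plus the small auxiliary
statistics (one-way ANOVA across regions, Spearman rank correlations).

Regions are always fitted independently; a region-year whose complete-case
plot count does not exceed the number of model variables is skipped with a
logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import landuse as lu
from .fit import FitResult, moments_from_table
from .io import AnalysisConfig, read_tables, write_results
from .metrics import metrics_table
from .models import (
    LATENT,
    PruneTrace,
    default_catalog,
    round_half_away,
    stepwise_prune,
    total_effect,
)

__all__ = [
    "StudyRun",
    "intensity_table",
    "build_plot_table",
    "run_study",
    "region_anova",
    "rank_correlation",
    "summary_report",
]

logger = logging.getLogger(__name__)

_EFFECT_TARGETS = (
    "plant_biomass",
    "plant_diversity",
    "herbivore_diversity",
    "predator_diversity",
)
_TABLE1_COLUMNS = (
    "plant_diversity",
    "plant_biomass",
    "herbivore_diversity",
    "herbivore_abundance",
    "herbivore_biomass",
    "predator_diversity",
    "predator_abundance",
    "predator_biomass",
)


@dataclass
class StudyRun:
    """Everything one full analysis produced, keyed by (region, year, model)."""

    config: AnalysisConfig
    plot_table: pd.DataFrame
    fits: dict[tuple[str, int, str], FitResult] = field(default_factory=dict)
    traces: dict[tuple[str, int, str], PruneTrace] = field(default_factory=dict)
    effects: pd.DataFrame | None = None
    fit_rows: pd.DataFrame | None = None
    skipped: list[tuple[str, int, str]] = field(default_factory=list)


def intensity_table(events: dict, config: AnalysisConfig, years: list[int]) -> pd.DataFrame:
    """Land-use intensity vectors for every plot-year with any event record."""
    by_plot: dict[str, dict[str, list]] = {}
    for kind in ("fertilize", "graze", "mow"):
        for ev in events[kind]:
            by_plot.setdefault(ev.plot, {"fertilize": [], "graze": [], "mow": []})[kind].append(ev)
    plot_region = events["plot_region"]
    rows = []
    for plot, evs in sorted(by_plot.items()):
        region = plot_region.get(plot, "")
        for year in years:
            s1, s2 = config.sampling_dates_for(year)
            onset = config.onset_date(region, year)
            rows.append(
                {
                    "plot": plot,
                    "region": region,
                    "year": year,
                    "fertilization": lu.fertilization_intensity(evs["fertilize"], year),
                    "grazing": lu.grazing_intensity(evs["graze"], year),
                    "mowing": lu.mowing_frequency(evs["mow"], year, s1),
                    "time_after_mowing": lu.time_after_mowing(evs["mow"], (s1, s2), onset),
                }
            )
    return pd.DataFrame(rows)


def build_plot_table(data_dir: str | Path, config: AnalysisConfig) -> pd.DataFrame:
    """Ingest the four CSVs and assemble the full plot-year variable table."""
    events, occurrences, surveys, traits = read_tables(data_dir, config)
    intensities = intensity_table(events, config, config.years)
    community = metrics_table(occurrences, surveys, traits, config.allometry)
    merged = intensities.merge(community, on=["plot", "year"], how="inner")
    logger.info("plot table: %d plot-years across %d plots", len(merged), merged["plot"].nunique())
    return merged


def _effect_sources(fit: FitResult) -> list[str]:
    """Latent land use when present; otherwise each management mode (the
    reporting convention for fallback fits)."""
    if fit.spec.latents:
        return [fit.spec.latents[0]]
    return ["fertilization", "grazing", "mowing"]


def _extra_pairs(model: str) -> list[tuple[str, str]]:
    pairs = [
        ("plant_diversity", "herbivore_diversity"),
        ("plant_diversity", "predator_diversity"),
    ]
    if model == "ra":
        pairs += [
            ("plant_biomass", "herbivore_diversity"),
            ("plant_biomass", "predator_diversity"),
            ("herbivore_biomass", "herbivore_diversity"),
            ("herbivore_biomass", "predator_diversity"),
        ]
    return pairs


def run_study(
    config: AnalysisConfig,
    data_dir: str | Path | None = None,
    plot_table: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> StudyRun:
    """Run the full analysis for every region, year and model variant.

    Either ``data_dir`` (the four CSVs) or a prebuilt ``plot_table`` must be
    given.  Writes metrics.csv, fit_results.csv and total_effects.csv when
    ``outdir`` is set.  Deterministic for a fixed config and inputs.
    """
    if plot_table is None:
        if data_dir is None:
            raise ValueError("need data_dir or plot_table")
        plot_table = build_plot_table(data_dir, config)
    run = StudyRun(config=config, plot_table=plot_table)
    catalog = default_catalog()

    effect_rows = []
    fit_rows = []
    for region in config.regions:
        for year in config.years:
            sub = plot_table[(plot_table["region"] == region) & (plot_table["year"] == year)]
            for model_name in config.model_variants:
                spec = catalog.rh_spec if model_name == "rh" else catalog.ra_spec
                if len(sub) <= len(spec.observed):
                    logger.warning(
                        "%s %s %s: %d plots <= %d variables, skipped",
                        region, year, model_name, len(sub), len(spec.observed),
                    )
                    run.skipped.append((region, year, model_name))
                    continue
                transforms = {v: spec.transform_of(v) for v in spec.observed}
                transforms.update({k: v for k, v in config.transforms.items() if k in spec.observed})
                moments = moments_from_table(sub, spec.observed, transforms)
                fit, trace = stepwise_prune(
                    spec, moments,
                    alpha_fit=config.alpha_fit,
                    gof_floor=config.gof_floor,
                    seed=config.seed,
                )
                key = (region, year, model_name)
                run.fits[key] = fit
                run.traces[key] = trace
                if trace.used_fallback:
                    logger.info("%s %s %s: latent replaced by indicator correlations", *key)
                for step in trace.steps:
                    logger.info(
                        "%s %s %s: deleted %s -> %s (AICc %.2f -> %.2f)",
                        region, year, model_name, *step.deleted,
                        step.aicc_before, step.aicc_after,
                    )
                fit_rows.extend(_fit_rows(key, fit, trace))
                if not fit.converged:
                    continue
                pairs = [
                    (s, t)
                    for s in _effect_sources(fit)
                    for t in _EFFECT_TARGETS
                    if t in fit.spec.observed
                ] + _extra_pairs(model_name)
                for source, target in pairs:
                    try:
                        dec = total_effect(fit, source, target)
                    except KeyError:
                        continue
                    effect_rows.append(
                        {
                            "region": region,
                            "year": year,
                            "model": model_name,
                            "source": "land_use" if source == LATENT else source,
                            "target": target,
                            "n_paths": dec.n_paths,
                            "total_effect": round_half_away(dec.total, 2),
                        }
                    )

    run.effects = pd.DataFrame(effect_rows)
    run.fit_rows = pd.DataFrame(fit_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary_report(plot_table, config).to_csv(outdir / "metrics.csv", index=False)
        run.fit_rows.to_csv(outdir / "fit_results.csv", index=False)
        write_results(run.effects, outdir / "total_effects.csv")
    return run


def _fit_rows(key: tuple[str, int, str], fit: FitResult, trace: PruneTrace) -> list[dict]:
    region, year, model = key
    base = {
        "region": region,
        "year": year,
        "model": model,
        "n_plots": fit.moments.N,
        "chi_square": fit.chi_square,
        "df": fit.df,
        "model_p_value": fit.model_p_value,
        "gof_index": fit.gof_index,
        "aicc": fit.aicc,
        "status": trace.status,
        "used_fallback": trace.used_fallback,
        "n_deleted": len(trace.steps),
    }
    rows = []
    if fit.converged:
        for _, p in fit.params.iterrows():
            rows.append(
                {
                    **base,
                    "parameter": p["name"],
                    "kind": p["kind"],
                    "estimate": p["estimate"],
                    "se": p["se"],
                    "p_value": p["p_value"],
                    "stars": p["stars"],
                    "std_estimate": p["std_estimate"],
                }
            )
    else:
        rows.append({**base, "parameter": "", "kind": "none"})
    return rows


# ---------------------------------------------------------------------------
# auxiliary statistics


def region_anova(values_by_region: dict[str, np.ndarray]) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of a plot-level variable across regions.

    Returns ``(F, (k-1, N-k), p)``; degenerate inputs (all values equal)
    raise ``ValueError``.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_region.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups with two values each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate: all values identical")
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    return float(F), (k - 1, len(pooled) - k), float(p)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def summary_report(plot_table: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Regional means ± SE per year with the across-region ANOVA row.

    The reporting surface of the study's summary table: one row per
    region-year with mean and standard error of every response variable,
    plus an ANOVA row per year carrying F, its df pair and p.
    """
    cols = [c for c in _TABLE1_COLUMNS if c in plot_table.columns]
    rows = []
    for year in config.years:
        sub_year = plot_table[plot_table["year"] == year]
        groups = {}
        for region in config.regions:
            sub = sub_year[sub_year["region"] == region]
            if sub.empty:
                continue
            groups[region] = sub
            row = {"year": year, "region": region, "statistic": "mean_se", "n_plots": len(sub)}
            for c in cols:
                row[f"{c}_mean"] = sub[c].mean()
                row[f"{c}_se"] = sub[c].std(ddof=1) / np.sqrt(len(sub))
            rows.append(row)
        if len(groups) >= 2:
            row = {"year": year, "region": "all", "statistic": "anova", "n_plots": len(sub_year)}
            for c in cols:
                try:
                    F, (d1, d2), p = region_anova({r: g[c].to_numpy() for r, g in groups.items()})
                except ValueError:
                    F, d1, d2, p = np.nan, np.nan, np.nan, np.nan
                row[f"{c}_mean"] = F
                row[f"{c}_se"] = p
            row["df"] = f"{d1},{d2}"
            rows.append(row)
    return pd.DataFrame(rows)
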