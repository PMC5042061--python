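"""End-to-end analysis pipeline: filters → size measures → beta diversity
→ predictor assembly → VIF screening → regression battery → resampling
null, with tidy CSV outputs and a JSON run log."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .beta import beta_matrix, family_incidence, mean_beta_per_lake
from .config import RunConfig
from .regress import build_predictor_table, ols_fit, run_model_battery, vif
from .resampling import resampling_battery
from .size import lake_size_summaries, shell_size, size_distribution_diagnostics
from .tables import ExclusionReport, apply_inclusion_filters, measured_richness

__all__ = ["AnalysisResults", "run_analysis", "write_results"]

RESAMPLING_PREDICTORS = ("log10_area", "pct_endemism")


@dataclass
class AnalysisResults:
    """Everything one pipeline run produces."""

    config: RunConfig
    exclusions: ExclusionReport
    size_summaries: pd.DataFrame
    beta: pd.DataFrame
    mean_beta: pd.Series
    predictors: pd.DataFrame
    vif: pd.Series
    battery: pd.DataFrame
    caspian_sensitivity: Optional[pd.DataFrame]
    resampling: Optional[pd.DataFrame]
    diagnostics: dict = field(default_factory=dict)


def _caspian_sensitivity(
    predictors: pd.DataFrame, summaries: pd.DataFrame, caspian_id: str
) -> Optional[pd.DataFrame]:
    """Re-fit the area simple regressions without the named lake."""
    if caspian_id not in predictors.index:
        return None
    keep = predictors.index.drop(caspian_id)
    rows = []
    for measure in ("s_range", "s_max"):
        y = summaries.loc[keep, measure]
        ok = y.notna()
        fit = ols_fit(predictors.loc[keep[ok], ["log10_area"]], y[ok].to_numpy())
        rows.append(
            {
                "size_measure": measure,
                "excluded_lake": caspian_id,
                "n": int(ok.sum()),
                "slope": fit.slope,
                "se": float(fit.bse["log10_area"]),
                "intercept": fit.intercept,
                "p": float(fit.pvalues["log10_area"]),
                "r2": fit.r2,
            }
        )
    return pd.DataFrame(rows)


def run_analysis(
    species: pd.DataFrame,
    lakes: pd.DataFrame,
    config: RunConfig | None = None,
    with_resampling: bool = True,
) -> AnalysisResults:
    """Run the full lake-level analysis on loaded tables."""
    config = config or RunConfig()
    species_f, lakes_f, report = apply_inclusion_filters(species, lakes, config)

    summaries = lake_size_summaries(
        species_f, s_range_mode=config.s_range_mode, s_mean_mode=config.s_mean_mode
    )
    incidence = family_incidence(species_f)
    beta = beta_matrix(incidence)
    mbeta = mean_beta_per_lake(beta)
    richness = measured_richness(species_f)
    predictors = build_predictor_table(lakes_f, mbeta, richness, config)

    vif_report = vif(predictors)
    battery = run_model_battery(predictors, summaries, config)
    caspian = _caspian_sensitivity(predictors, summaries, config.caspian_lake_id)

    resamp = None
    if with_resampling:
        resamp = resampling_battery(
            species_f,
            predictors[list(RESAMPLING_PREDICTORS)],
            config=config,
            seed=config.seed,
        )

    pooled = np.log10(
        shell_size(species_f["height"].to_numpy(), species_f["width"].to_numpy())
    )
    diag = size_distribution_diagnostics(pooled)
    diagnostics = {
        "pooled_n": diag.n,
        "pooled_skewness_g1": diag.skewness_g1,
        "pooled_shapiro_w": diag.shapiro_w,
        "pooled_shapiro_p": diag.shapiro_p,
        "exclusion_pct_no_size": round(report.pct_no_size, 1),
    }
    return AnalysisResults(
        config=config,
        exclusions=report,
        size_summaries=summaries,
        beta=beta,
        mean_beta=mbeta,
        predictors=predictors,
        vif=vif_report,
        battery=battery,
        caspian_sensitivity=caspian,
        resampling=resamp,
        diagnostics=diagnostics,
    )


def write_results(results: AnalysisResults, outdir: str | Path) -> None:
    """Write every result table as CSV plus a JSON run log.

    Display files carry 3 decimals (`*_display.csv` for the battery);
    companion files keep full precision.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.size_summaries.round(6).to_csv(out / "size_summaries.csv")
    results.beta.to_csv(out / "beta_matrix.csv")
    results.mean_beta.to_csv(out / "mean_beta.csv")
    results.predictors.to_csv(out / "predictors.csv")
    results.vif.to_csv(out / "vif.csv", header=True)
    results.battery.to_csv(out / "table2_replica_full.csv", index=False)
    display = results.battery.copy()
    num = display.select_dtypes(float).columns
    display[num] = display[num].round(3)
    display.to_csv(out / "table2_replica.csv", index=False)
    if results.caspian_sensitivity is not None:
        results.caspian_sensitivity.to_csv(out / "caspian_sensitivity.csv", index=False)
    if results.resampling is not None:
        results.resampling.to_csv(out / "resampling.csv", index=False)

    log = {
        "config": results.config.to_dict(),
        "exclusions": results.exclusions.to_dict(),
        "diagnostics": results.diagnostics,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
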