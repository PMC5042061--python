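"""Family-stratified and temporal analyses.

Four follow-up questions around the main battery:

* does the size–richness/area relationship hold within individual
  gastropod families (only families present in more than five lakes;
  (family, lake) cells with a single species carry no range and are
  dropped);
* does a species' stratigraphic longevity (max − min occurrence age,
  Myr; occurrences dated with > 3 Myr uncertainty excluded) predict its
  size;
* do a fauna's size measures change with the age of the lake at a given
  stratigraphic horizon;
* do sizes trend along clade rank within phylogenetic lineages (rank =
  number of measurable speciation events from the lineage's first
  species).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .regress import RegressionResult, ols_fit
from .size import SIZE_MEASURES, fauna_size_summary, lake_size_summaries, shell_size

__all__ = [
    "family_subsets",
    "family_level_battery",
    "longevity_records",
    "species_longevity_regression",
    "horizon_faunas",
    "lake_age_regressions",
    "clade_rank_trend",
]


def family_subsets(
    species: pd.DataFrame,
    min_lakes: int = 6,
    min_cell_species: int = 2,
) -> dict[str, pd.DataFrame]:
    """Per-family species subsets passing the stratified-analysis filters.

    (family, lake) cells with fewer than ``min_cell_species`` measured
    species are dropped first (no size range there); a family must then
    still occur in at least ``min_lakes`` lakes.  The two filters commute.
    """
    df = species[~species["size_missing"]] if "size_missing" in species.columns else species
    out: dict[str, pd.DataFrame] = {}
    for family, grp in df.groupby("family"):
        counts = grp.groupby("lake_id").size()
        keep_lakes = counts[counts >= min_cell_species].index
        sub = grp[grp["lake_id"].isin(keep_lakes)]
        if sub["lake_id"].nunique() >= min_lakes:
            out[family] = sub.copy()
    return out


def family_level_battery(
    species: pd.DataFrame,
    lakes: pd.DataFrame,
    config: RunConfig | None = None,
    min_retained_lakes: int = 3,
) -> pd.DataFrame:
    """Simple regressions per family: each size measure of the family's
    per-lake subset on the lake-level parameters that matter in the main
    battery — log10 overall measured richness and log10 lake area.

    Families retained by :func:`family_subsets`; a family whose measures
    are all-missing or that keeps fewer than ``min_retained_lakes`` lakes
    for a given response is skipped with a note.
    """
    from .tables import measured_richness

    config = config or RunConfig()
    area = lakes.set_index("lake_id")["area"].astype(float)
    richness = measured_richness(species).astype(float)
    rows = []
    for family, sub in family_subsets(
        species, min_lakes=config.family_min_lakes
    ).items():
        summaries = lake_size_summaries(
            sub, s_range_mode=config.s_range_mode, s_mean_mode=config.s_mean_mode
        )
        predictors = pd.DataFrame(
            {
                "log10_richness": np.log10(richness.reindex(summaries.index)),
                "log10_area": np.log10(area.reindex(summaries.index)),
            }
        )
        for measure in SIZE_MEASURES:
            for pred in predictors.columns:
                y = summaries[measure]
                ok = y.notna() & predictors[pred].notna()
                if ok.sum() < min_retained_lakes:
                    warnings.warn(
                        f"family {family!r}: fewer than {min_retained_lakes} lakes "
                        f"for {measure} ~ {pred}; skipped"
                    )
                    continue
                fit = ols_fit(predictors.loc[ok, [pred]], y[ok].to_numpy())
                rows.append(
                    {
                        "family": family,
                        "size_measure": measure,
                        "predictor": pred,
                        "n_lakes": int(ok.sum()),
                        "slope": fit.slope,
                        "se": float(fit.bse[pred]),
                        "intercept": fit.intercept,
                        "p": float(fit.pvalues[pred]),
                        "r2": fit.r2,
                        "r2_adj": fit.r2_adj,
                    }
                )
    return pd.DataFrame(rows)


def longevity_records(
    species: pd.DataFrame, max_age_uncertainty: float = 3.0
) -> pd.DataFrame:
    """Species-level longevity (Myr) and size from occurrence ages.

    Occurrence ages are Ma before present; longevity pools each species'
    qualifying occurrences (dating uncertainty ≤ ``max_age_uncertainty``)
    across lakes and takes max(first_age) − min(last_age).  Single-horizon
    species get longevity 0 and are retained.
    """
    df = species[~species["size_missing"]] if "size_missing" in species.columns else species
    df = df[df["first_age"].notna() & df["last_age"].notna()]
    unc = df["age_uncertainty"].astype(float)
    df = df[unc.isna() | (unc <= max_age_uncertainty)]
    if df.empty:
        return pd.DataFrame(columns=["species_id", "longevity", "S"])
    s = shell_size(df["height"].to_numpy(), df["width"].to_numpy())
    df = df.assign(S=s)
    grouped = df.groupby("species_id").agg(
        first=("first_age", "max"), last=("last_age", "min"), S=("S", "max")
    )
    out = pd.DataFrame(
        {
            "species_id": grouped.index,
            "longevity": (grouped["first"] - grouped["last"]).to_numpy(),
            "S": grouped["S"].to_numpy(),
        }
    ).reset_index(drop=True)
    if (out["longevity"] < 0).any():
        raise ValueError("negative longevity; check first_age/last_age orientation")
    return out


def species_longevity_regression(
    records: pd.DataFrame, min_records: int = 10
) -> RegressionResult:
    """OLS of log10 size on stratigraphic longevity (Myr)."""
    if len(records) < min_records:
        raise ValueError(f"need at least {min_records} longevity records")
    if np.allclose(records["longevity"], 0.0):
        raise ValueError("all longevities are zero; regression undefined")
    X = records[["longevity"]].astype(float)
    y = np.log10(records["S"].to_numpy(dtype=float))
    return ols_fit(X, y)


def horizon_faunas(
    species: pd.DataFrame,
    lakes: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-(lake, horizon) size summaries with the lake's age at that time.

    Horizon membership comes from the species table's ``horizon`` column
    (a label) with ``first_age`` as the horizon age; the lake's age at the
    horizon is ``age_base − horizon age`` (Myr since lake origin), so the
    lake table must carry ``age_base``.
    """
    config = config or RunConfig()
    df = species[~species["size_missing"]] if "size_missing" in species.columns else species
    df = df[df["horizon"].notna()]
    if df.empty:
        return pd.DataFrame(
            columns=["lake_id", "horizon", "horizon_age", "lake_age", "n_measured"]
            + list(SIZE_MEASURES)
        )
    if "age_base" not in lakes.columns or lakes["age_base"].isna().all():
        raise ValueError("lake table needs age_base for horizon analyses")
    base = lakes.set_index("lake_id")["age_base"].astype(float)

    rows = []
    for (lake, horizon), grp in df.groupby(["lake_id", "horizon"]):
        ages = grp["first_age"].astype(float)
        if ages.isna().all():
            raise ValueError(f"horizon {horizon!r} in {lake!r} has no dated occurrences")
        horizon_age = float(ages.mean())
        lake_age = float(base[lake]) - horizon_age
        if lake_age < 0:
            raise ValueError(
                f"horizon {horizon!r} predates lake {lake!r} (age_base {base[lake]})"
            )
        s = shell_size(grp["height"].to_numpy(), grp["width"].to_numpy())
        summ = fauna_size_summary(
            s, s_range_mode=config.s_range_mode, s_mean_mode=config.s_mean_mode
        )
        rows.append(
            {
                "lake_id": lake,
                "horizon": horizon,
                "horizon_age": horizon_age,
                "lake_age": lake_age,
                "n_measured": summ.n_measured,
                "s_range": summ.s_range,
                "s_max": summ.s_max,
                "s_min": summ.s_min,
                "s_mean": summ.s_mean,
            }
        )
    return pd.DataFrame(rows)


def lake_age_regressions(horizons: pd.DataFrame) -> pd.DataFrame:
    """OLS of each size measure on the lake's age at the horizon (Myr)."""
    if len(horizons) < 3:
        raise ValueError("need at least three horizons for a regression")
    if horizons["lake_id"].nunique() == 1:
        warnings.warn("all horizons come from a single lake; no between-lake replication")
    rows = []
    for measure in SIZE_MEASURES:
        ok = horizons[measure].notna()
        fit = ols_fit(
            horizons.loc[ok, ["lake_age"]], horizons.loc[ok, measure].to_numpy()
        )
        rows.append(
            {
                "size_measure": measure,
                "n": int(ok.sum()),
                "slope": fit.slope,
                "se": float(fit.bse["lake_age"]),
                "intercept": fit.intercept,
                "p": float(fit.pvalues["lake_age"]),
                "r2": fit.r2,
                "r2_adj": fit.r2_adj,
            }
        )
    return pd.DataFrame(rows)


def clade_rank_trend(lineage: pd.DataFrame) -> RegressionResult:
    """OLS of log10 size on clade rank within one lineage.

    ``lineage`` needs columns ``clade_rank`` (positive integers) and ``S``
    (mm).  A positive slope indicates size increase over the lineage's
    speciation sequence.
    """
    ranks = lineage["clade_rank"].astype(float)
    if ranks.nunique() < 3:
        raise ValueError("need at least 3 distinct clade ranks")
    y = np.log10(lineage["S"].to_numpy(dtype=float))
    return ols_fit(lineage[["clade_rank"]].astype(float), y)
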