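"""OLS regression battery, multicollinearity screening and hierarchical
partitioning of predictor contributions.

The central analysis asks which lake/fauna characteristics predict the
four per-fauna size measures.  For each size measure we fit one multiple
regression on all seven predictors plus seven simple regressions, and
decompose the multiple model's R² into per-predictor *independent*
contributions by hierarchical partitioning: I_j is the average, over all
k! orders in which predictors can enter the model, of the R² gain when
predictor j enters; the *joint* contribution J_j is the remainder of j's
marginal R².  Two identities hold exactly: ΣI = R²(full model), and
I_j + J_j = marginal R²_j for each predictor.

Predictors (one row per lake): log10 area (km²), mean family-level β_jac,
log10 distance to the closest coeval lake (km), percent endemism,
latitude, longitude, and log10 measured species richness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig
from .size import SIZE_MEASURES

__all__ = [
    "RegressionResult",
    "PartitionResult",
    "ols_fit",
    "vif",
    "HierarchicalPartitioner",
    "hierarchical_partition",
    "PREDICTOR_ORDER",
    "build_predictor_table",
    "run_model_battery",
]

# Table layout order of the seven predictors.
PREDICTOR_ORDER = (
    "log10_area",
    "mean_beta",
    "log10_distance",
    "pct_endemism",
    "latitude",
    "longitude",
    "log10_richness",
)


@dataclass
class RegressionResult:
    """Classical OLS report for one fitted model."""

    params: pd.Series  # includes "const"
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    f_stat: float
    f_pvalue: float
    n: int
    df_model: int
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def slope(self) -> float:
        """Slope of the (single) predictor in a simple regression."""
        names = [n for n in self.params.index if n != "const"]
        if len(names) != 1:
            raise ValueError("slope is only defined for a simple regression")
        return float(self.params[names[0]])

    @property
    def intercept(self) -> float:
        return float(self.params["const"])


def _as_design(design) -> pd.DataFrame:
    X = pd.DataFrame(design)
    if X.columns.dtype != object:
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    return X.astype(float)


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        guilty = []
        cols = X.to_numpy()
        for j, name in enumerate(X.columns):
            others = np.column_stack(
                [np.ones(len(X)), np.delete(cols, j, axis=1)]
            )
            fitted = others @ np.linalg.lstsq(others, cols[:, j], rcond=None)[0]
            sse = float(((cols[:, j] - fitted) ** 2).sum())
            sst = float(((cols[:, j] - cols[:, j].mean()) ** 2).sum())
            if sst == 0.0 or sse <= 1e-10 * max(sst, 1.0):
                guilty.append(name)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {guilty}"
        )


def ols_fit(design, response, check_rank: bool = True) -> RegressionResult:
    """Fit y = b0 + X b by least squares with classical (homoskedastic)
    standard errors, two-sided t tests per coefficient and the overall F
    test.  ``design`` is a DataFrame (or array) of predictor columns
    without the constant.
    """
    X = _as_design(design)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("response length does not match design rows")
    if n < k + 2:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    if np.isnan(X.to_numpy()).any() or np.isnan(y).any():
        raise ValueError("design and response must not contain missing values")
    if check_rank:
        _check_full_rank(X)

    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    fit = model.fit()
    # A constant response has zero total sum of squares; the model explains
    # nothing and we report R² = 0 rather than an undefined ratio.
    degenerate = float(((y - y.mean()) ** 2).sum()) == 0.0
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r2=0.0 if degenerate else float(fit.rsquared),
        r2_adj=0.0 if degenerate else float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        n=int(n),
        df_model=int(fit.df_model),
        residuals=np.asarray(fit.resid),
    )


def vif(design) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 − R²_j).

    R²_j comes from regressing predictor j (with intercept) on all other
    predictors.  Exactly collinear predictors get ``inf``.
    """
    X = _as_design(design)
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least two predictors")
    if n <= k:
        raise ValueError("VIF needs more observations than predictors")
    out = {}
    cols = X.to_numpy()
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(cols, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, cols[:, j], rcond=None)
        resid = cols[:, j] - others @ coef
        sst = float(((cols[:, j] - cols[:, j].mean()) ** 2).sum())
        if sst == 0.0:
            raise ValueError(f"predictor {name!r} is constant")
        r2_j = 1.0 - float((resid**2).sum()) / sst
        out[name] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return pd.Series(out, name="vif")


@dataclass
class PartitionResult:
    """Hierarchical-partitioning decomposition of a multiple regression."""

    independent: pd.Series  # I_j, in R² units
    joint: pd.Series  # J_j = marginal R²_j − I_j
    independent_pct: pd.Series  # 100 · I_j / ΣI
    r2_full: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "independent": self.independent,
                "joint": self.joint,
                "independent_pct": self.independent_pct,
            }
        )


def _subset_r2(X: np.ndarray, y: np.ndarray) -> dict[frozenset, float]:
    """R² of every predictor subset (with intercept); empty subset → 0."""
    n, k = X.shape
    y_c = y - y.mean()
    sst = float((y_c**2).sum())
    if sst == 0.0:
        raise ValueError("response has zero variance")
    r2 = {frozenset(): 0.0}
    ones = np.ones((n, 1))
    for m in range(1, k + 1):
        for subset in combinations(range(k), m):
            design = np.hstack([ones, X[:, subset]])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise np.linalg.LinAlgError(
                    f"rank-deficient subset fit for predictors {subset}"
                )
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            r2[frozenset(subset)] = 1.0 - float((resid**2).sum()) / sst
    return r2


class HierarchicalPartitioner(BaseEstimator):
    """Decompose a linear model's R² into per-predictor contributions.

    Fits all 2^k predictor subsets and averages, over every entry order,
    the R² increase attributable to each predictor (equivalently, a
    subset-size-weighted average over subsets).  Negative independent
    contributions are mathematically possible and are reported as-is.

    Parameters
    ----------
    max_predictors : int
        Guard on the 2^k subset enumeration (default 12).

    Attributes
    ----------
    independent_ : pd.Series
        Independent contribution I_j of each predictor, in R² units.
    joint_ : pd.Series
        Joint contribution J_j = (marginal R² of j) − I_j.
    independent_pct_ : pd.Series
        I_j as a percentage of ΣI.
    r2_full_ : float
        R² of the full model; equals ΣI to numerical precision.
    feature_names_in_ : ndarray of str
    n_features_in_ : int
    """

    def __init__(self, max_predictors: int = 12):
        self.max_predictors = max_predictors

    def fit(self, X, y):
        Xf = _as_design(X)
        y = np.asarray(y, dtype=float)
        n, k = Xf.shape
        if not 1 <= k <= self.max_predictors:
            raise ValueError(
                f"k={k} predictors outside [1, {self.max_predictors}] "
                "(2^k subset fits)"
            )
        if n < k + 2:
            raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
        names = list(Xf.columns)
        mat = Xf.to_numpy()
        r2 = _subset_r2(mat, y)

        indep = np.zeros(k)
        for j in range(k):
            rest = [i for i in range(k) if i != j]
            total = 0.0
            for m in range(k):
                w = factorial(m) * factorial(k - m - 1) / factorial(k)
                for subset in combinations(rest, m):
                    s = frozenset(subset)
                    total += w * (r2[s | {j}] - r2[s])
            indep[j] = total
        marginal = np.array([r2[frozenset({j})] for j in range(k)])
        joint = marginal - indep

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = k
        self.independent_ = pd.Series(indep, index=names, name="independent")
        self.joint_ = pd.Series(joint, index=names, name="joint")
        total_i = indep.sum()
        pct = 100.0 * indep / total_i if total_i != 0 else np.full(k, np.nan)
        self.independent_pct_ = pd.Series(pct, index=names, name="independent_pct")
        self.r2_full_ = float(r2[frozenset(range(k))])
        return self

    def partition_(self) -> PartitionResult:
        check_is_fitted(self, "independent_")
        return PartitionResult(
            independent=self.independent_,
            joint=self.joint_,
            independent_pct=self.independent_pct_,
            r2_full=self.r2_full_,
        )


def hierarchical_partition(design, response) -> PartitionResult:
    """Functional wrapper over :class:`HierarchicalPartitioner`."""
    return HierarchicalPartitioner().fit(design, response).partition_()


def build_predictor_table(
    lakes: pd.DataFrame,
    mean_beta: pd.Series,
    richness: pd.Series,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Assemble the per-lake predictor table in model units.

    Area, distance and measured richness enter log10-transformed; percent
    endemism, latitude, longitude and mean β_jac enter raw (the log10 set
    is configurable).  Indexed by lake_id, columns in table order.
    """
    config = config or RunConfig()
    lk = lakes.set_index("lake_id")
    logged = set(config.log10_predictors)

    def maybe_log(series: pd.Series, raw_name: str) -> pd.Series:
        if raw_name in logged:
            if (series <= 0).any():
                raise ValueError(f"{raw_name} must be > 0 for log10 transform")
            return np.log10(series.astype(float))
        return series.astype(float)

    table = pd.DataFrame(
        {
            "log10_area": maybe_log(lk["area"], "area"),
            "mean_beta": mean_beta.reindex(lk.index),
            "log10_distance": maybe_log(lk["distance"], "distance"),
            "pct_endemism": lk["pct_endemism"].astype(float),
            "latitude": lk["latitude"].astype(float),
            "longitude": lk["longitude"].astype(float),
            "log10_richness": maybe_log(
                richness.reindex(lk.index).astype(float), "n_species"
            ),
        }
    )
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(f"missing predictor cells for lake(s): {bad}")
    return table


def run_model_battery(
    predictors: pd.DataFrame,
    size_summaries: pd.DataFrame,
    config: RunConfig | None = None,
    measures: Sequence[str] = SIZE_MEASURES,
) -> pd.DataFrame:
    """Fit the full battery: per size measure, one multiple regression on
    all predictors (with hierarchical partitioning) and one simple
    regression per predictor.

    Returns a tidy frame with one row per (size measure, predictor):
    model-level stats (R², R²_adj, F, P, n) repeated within each block,
    multiple-regression slope/SE/P, independent contribution I (%), and
    the simple-regression slope/SE, intercept/SE, P and R².
    """
    config = config or RunConfig()
    rows = []
    for measure in measures:
        y_all = size_summaries[measure]
        keep = y_all.notna()
        idx = size_summaries.index[keep].intersection(predictors.index)
        X = predictors.loc[idx]
        y = y_all.loc[idx].to_numpy(dtype=float)
        if len(idx) < X.shape[1] + 2:
            raise ValueError(
                f"{measure}: only {len(idx)} lakes for {X.shape[1]} predictors"
            )
        full = ols_fit(X, y)
        part = hierarchical_partition(X, y)
        for var in X.columns:
            simple = ols_fit(X[[var]], y)
            rows.append(
                {
                    "size_measure": measure,
                    "variable": var,
                    "n": full.n,
                    "model_r2": full.r2,
                    "model_r2_adj": full.r2_adj,
                    "model_f": full.f_stat,
                    "model_p": full.f_pvalue,
                    "mr_slope": float(full.params[var]),
                    "mr_se": float(full.bse[var]),
                    "mr_p": float(full.pvalues[var]),
                    "i_pct": float(part.independent_pct[var]),
                    "lr_slope": simple.slope,
                    "lr_se": float(simple.bse[var]),
                    "lr_intercept": simple.intercept,
                    "lr_intercept_se": float(simple.bse["const"]),
                    "lr_p": float(simple.pvalues[var]),
                    "lr_r2": simple.r2,
                }
            )
    return pd.DataFrame(rows)
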