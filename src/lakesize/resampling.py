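"""Subsample-resampling null test for richness-driven size correlations.

Because species richness rises steeply with lake area (and endemism is
correlated with richness), a correlation between a fauna's size extremes
and area could be a pure sampling artifact: more species means more draws
from the size distribution, hence larger expected maxima and smaller
expected minima.  The test randomly resamples a fixed fraction (default
25%) of each lake's species without replacement, recomputes the per-fauna
size measures, refits the simple regression, and repeats this 1000 times.
The P value is the proportion of resampled slopes strictly greater than
the observed slope; the null model is that the observed correlation is
independent of species richness.

Reproducibility contract: one master seed; each replicate draws from its
own deterministically derived stream, so results are independent of
evaluation order and shared across the measure × predictor combinations
of one battery (every combination sees the same subsampled faunas, as in
a single pass over the data).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig
from .size import SIZE_MEASURES, fauna_size_summary, shell_size

__all__ = [
    "subsample_fauna",
    "ResamplingResult",
    "ResamplingNull",
    "resampling_test",
    "resampling_battery",
]


def subsample_fauna(values, fraction: float, min_n: int, rng: np.random.Generator):
    """Random subsample without replacement of size max(min_n, ceil(fraction·n)).

    Raises if the fauna has fewer than ``min_n`` species (the caller drops
    such lakes from the replicate).
    """
    v = np.asarray(values)
    n = v.size
    if n < min_n:
        raise ValueError(f"fauna of {n} species is below the minimum of {min_n}")
    size = min(n, max(min_n, ceil(fraction * n)))
    if size == n:
        return v.copy()
    return rng.choice(v, size=size, replace=False)


@dataclass
class ResamplingResult:
    """Outcome of one measure × predictor resampling test."""

    measure: str
    predictor: str
    observed_slope: float
    resampled_slopes: np.ndarray  # NaN where the replicate was discarded
    p_value: float
    fraction: float
    repetitions: int
    seed: Optional[int]
    mode: str
    n_discarded: int


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form simple-regression slope Sxy / Sxx."""
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    if sxx == 0.0:
        return np.nan
    return float((xc * (y - y.mean())).sum() / sxx)


def _measure_row(sizes: np.ndarray, s_range_mode: str, s_mean_mode: str) -> dict:
    s = fauna_size_summary(sizes, s_range_mode=s_range_mode, s_mean_mode=s_mean_mode)
    return {"s_range": s.s_range, "s_max": s.s_max, "s_min": s.s_min, "s_mean": s.s_mean}


def _p_value(resampled: np.ndarray, observed: float, mode: str, repetitions: int) -> float:
    valid = resampled[~np.isnan(resampled)]
    if mode == "literal":
        count = int((valid > observed).sum())
    elif mode == "two_sided_magnitude":
        count = int((np.abs(valid) > abs(observed)).sum())
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return count / repetitions


def _run_battery(
    sizes_by_lake: dict[str, np.ndarray],
    predictors: pd.DataFrame,
    measures: Sequence[str],
    fraction: float,
    repetitions: int,
    min_n: int,
    mode: str,
    seed: Optional[int],
    s_range_mode: str,
    s_mean_mode: str,
) -> tuple[list[ResamplingResult], pd.DataFrame]:
    lakes = [lk for lk in predictors.index if lk in sizes_by_lake]
    eligible = [lk for lk in lakes if sizes_by_lake[lk].size >= min_n]
    if len(eligible) < 3:
        raise ValueError("fewer than 3 lakes are large enough to subsample")

    observed = pd.DataFrame(
        {
            lk: _measure_row(sizes_by_lake[lk], s_range_mode, s_mean_mode)
            for lk in lakes
        }
    ).T

    streams = np.random.SeedSequence(seed).spawn(repetitions)
    combos = [(m, p) for m in measures for p in predictors.columns]
    slopes = {c: np.full(repetitions, np.nan) for c in combos}

    for rep in range(repetitions):
        rng = np.random.default_rng(streams[rep])
        rows = {
            lk: _measure_row(
                subsample_fauna(sizes_by_lake[lk], fraction, min_n, rng),
                s_range_mode,
                s_mean_mode,
            )
            for lk in eligible
        }
        resampled = pd.DataFrame(rows).T
        for measure, pred in combos:
            y = resampled[measure].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 3:
                continue  # replicate discarded for this combination
            x = predictors.loc[resampled.index[ok], pred].to_numpy(dtype=float)
            slopes[(measure, pred)][rep] = _slope(x, y[ok])

    results = []
    for measure, pred in combos:
        y = observed[measure].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        x = predictors.loc[observed.index[ok], pred].to_numpy(dtype=float)
        obs = _slope(x, y[ok])
        vec = slopes[(measure, pred)]
        results.append(
            ResamplingResult(
                measure=measure,
                predictor=pred,
                observed_slope=obs,
                resampled_slopes=vec,
                p_value=_p_value(vec, obs, mode, repetitions),
                fraction=fraction,
                repetitions=repetitions,
                seed=seed,
                mode=mode,
                n_discarded=int(np.isnan(vec).sum()),
            )
        )
    return results, observed


class ResamplingNull(BaseEstimator):
    """One measure × predictor subsample-resampling test.

    Parameters mirror the study procedure: ``fraction`` of each fauna is
    resampled without replacement (floored at ``min_n`` species),
    ``repetitions`` times.  ``mode="literal"`` counts resampled slopes
    strictly greater than the observed slope; ``"two_sided_magnitude"``
    compares absolute values.

    Attributes
    ----------
    observed_slope_ : float
    resampled_slopes_ : ndarray, length ``repetitions`` (NaN = discarded)
    p_value_ : float
    n_discarded_ : int
    """

    def __init__(
        self,
        measure: str = "s_range",
        fraction: float = 0.25,
        repetitions: int = 1000,
        min_n: int = 2,
        mode: str = "literal",
        random_state: Optional[int] = None,
        s_range_mode: str = "raw_difference",
        s_mean_mode: str = "arithmetic",
    ):
        self.measure = measure
        self.fraction = fraction
        self.repetitions = repetitions
        self.min_n = min_n
        self.mode = mode
        self.random_state = random_state
        self.s_range_mode = s_range_mode
        self.s_mean_mode = s_mean_mode

    def fit(self, species: pd.DataFrame, predictor: pd.Series):
        """Run the test.

        ``species`` is a filtered species table (lake_id, height, width);
        ``predictor`` is the per-lake predictor in model units (e.g.
        log10 area), indexed by lake_id and named.
        """
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        name = predictor.name or "predictor"
        sizes = _sizes_by_lake(species)
        results, _ = _run_battery(
            sizes,
            predictor.to_frame(name),
            [self.measure],
            self.fraction,
            self.repetitions,
            self.min_n,
            self.mode,
            self.random_state,
            self.s_range_mode,
            self.s_mean_mode,
        )
        res = results[0]
        self.observed_slope_ = res.observed_slope
        self.resampled_slopes_ = res.resampled_slopes
        self.p_value_ = res.p_value
        self.n_discarded_ = res.n_discarded
        self.result_ = res
        return self

    def result(self) -> ResamplingResult:
        check_is_fitted(self, "result_")
        return self.result_


def _sizes_by_lake(species: pd.DataFrame) -> dict[str, np.ndarray]:
    df = species
    if "size_missing" in df.columns:
        df = df[~df["size_missing"]]
    s = shell_size(df["height"].to_numpy(), df["width"].to_numpy())
    frame = pd.DataFrame({"lake_id": df["lake_id"].to_numpy(), "S": s})
    return {lk: grp["S"].to_numpy() for lk, grp in frame.groupby("lake_id")}


def resampling_test(
    species: pd.DataFrame,
    predictor: pd.Series,
    measure: str = "s_range",
    config: RunConfig | None = None,
    seed: Optional[int] = None,
) -> ResamplingResult:
    """Functional wrapper over :class:`ResamplingNull` using a RunConfig."""
    config = config or RunConfig()
    est = ResamplingNull(
        measure=measure,
        fraction=config.resample_fraction,
        repetitions=config.resample_reps,
        min_n=config.min_subsample,
        mode=config.resampling_mode,
        random_state=seed if seed is not None else config.seed,
        s_range_mode=config.s_range_mode,
        s_mean_mode=config.s_mean_mode,
    )
    return est.fit(species, predictor).result()


def resampling_battery(
    species: pd.DataFrame,
    predictors: pd.DataFrame,
    measures: Sequence[str] = SIZE_MEASURES,
    config: RunConfig | None = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """All measure × predictor tests sharing subsampled faunas.

    Each replicate resamples every lake once and evaluates every
    combination on the same subsamples (one pass, as in a single run of
    the study procedure).  Returns a tidy frame of observed slopes and
    P values.
    """
    config = config or RunConfig()
    sizes = _sizes_by_lake(species)
    results, _ = _run_battery(
        sizes,
        predictors,
        list(measures),
        config.resample_fraction,
        config.resample_reps,
        config.min_subsample,
        config.resampling_mode,
        seed if seed is not None else config.seed,
        config.s_range_mode,
        config.s_mean_mode,
    )
    return pd.DataFrame(
        [
            {
                "size_measure": r.measure,
                "predictor": r.predictor,
                "observed_slope": r.observed_slope,
                "p_value": r.p_value,
                "fraction": r.fraction,
                "repetitions": r.repetitions,
                "n_discarded": r.n_discarded,
                "mode": r.mode,
            }
            for r in results
        ]
    )
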