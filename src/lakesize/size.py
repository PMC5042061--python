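"""Shell-size estimator and per-fauna size measures.

A shell recorded as height *h* × width *w* (mm) is summarised by the side
length of the square with the same area as that rectangle,

    S = sqrt(h · w)   [mm],

which makes planispiral (wide, low) and turriform (tall, narrow) shells
comparable on one axis.  Each lake fauna is then described by four
log10-transformed measures: S_mean (log10 of the arithmetic mean of raw
S), S_max, S_min, and S_range (log10 of the raw max − min spread).
S_range is undefined for faunas of a single species or with zero raw
spread and is reported as missing there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shell_size",
    "FaunaSizeSummary",
    "fauna_size_summary",
    "lake_size_summaries",
    "SIZE_MEASURES",
    "skewness_g1",
    "normality_test",
    "SizeDistributionDiagnostics",
    "size_distribution_diagnostics",
]

SIZE_MEASURES = ("s_range", "s_max", "s_min", "s_mean")


def shell_size(height, width):
    """Equal-area size estimator S = sqrt(height * width), in mm.

    Symmetric in its arguments and scale-equivariant:
    ``shell_size(k*h, k*w) == k * shell_size(h, w)``.
    Accepts scalars or arrays; every input must be strictly positive.
    """
    h = np.asarray(height, dtype=float)
    w = np.asarray(width, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("height and width must be strictly positive (mm)")
    out = np.sqrt(h * w)
    return float(out) if out.ndim == 0 else out


@dataclass
class FaunaSizeSummary:
    """The four log10 size measures of one lake fauna."""

    lake_id: Optional[str]
    n_measured: int
    s_mean: float
    s_max: float
    s_min: float
    s_range: float  # NaN when n < 2 or raw max == raw min

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def fauna_size_summary(
    sizes: Sequence[float],
    lake_id: Optional[str] = None,
    s_range_mode: str = "raw_difference",
    s_mean_mode: str = "arithmetic",
) -> FaunaSizeSummary:
    """Summarise one lake's raw S values (mm) into the four log10 measures.

    ``s_range_mode="raw_difference"`` (default) takes log10(max − min);
    ``"log_difference"`` takes log10(max) − log10(min).  ``s_mean_mode``
    selects log10 of the arithmetic mean of raw S (default) or the mean of
    log10 S (geometric mean).
    """
    s = np.asarray(sizes, dtype=float)
    if s.size == 0:
        raise ValueError("fauna has no measured species")
    if np.any(s <= 0) or np.any(~np.isfinite(s)):
        raise ValueError("all sizes must be finite and > 0 (mm)")

    smax, smin = float(s.max()), float(s.min())
    if s_mean_mode == "arithmetic":
        s_mean = float(np.log10(s.mean()))
    elif s_mean_mode == "geometric":
        s_mean = float(np.mean(np.log10(s)))
    else:
        raise ValueError(f"unknown s_mean_mode {s_mean_mode!r}")

    if s.size < 2 or smax == smin:
        s_range = np.nan
    elif s_range_mode == "raw_difference":
        s_range = float(np.log10(smax - smin))
    elif s_range_mode == "log_difference":
        s_range = float(np.log10(smax) - np.log10(smin))
    else:
        raise ValueError(f"unknown s_range_mode {s_range_mode!r}")

    return FaunaSizeSummary(
        lake_id=lake_id,
        n_measured=int(s.size),
        s_mean=s_mean,
        s_max=float(np.log10(smax)),
        s_min=float(np.log10(smin)),
        s_range=s_range,
    )


def lake_size_summaries(
    species: pd.DataFrame,
    s_range_mode: str = "raw_difference",
    s_mean_mode: str = "arithmetic",
) -> pd.DataFrame:
    """Per-lake size summaries from a (filtered) species table.

    Adds an ``S`` column view internally via :func:`shell_size`; returns a
    DataFrame indexed by lake with columns ``n_measured, s_mean, s_max,
    s_min, s_range``.
    """
    ok = species[~species["size_missing"]] if "size_missing" in species.columns else species
    s_values = shell_size(ok["height"].to_numpy(), ok["width"].to_numpy())
    frame = pd.DataFrame({"lake_id": ok["lake_id"].to_numpy(), "S": s_values})
    rows = [
        fauna_size_summary(
            grp["S"].to_numpy(), lake_id=lake, s_range_mode=s_range_mode, s_mean_mode=s_mean_mode
        ).to_dict()
        for lake, grp in frame.groupby("lake_id", sort=True)
    ]
    return pd.DataFrame(rows).set_index("lake_id")


def skewness_g1(values) -> float:
    """Adjusted Fisher–Pearson sample skewness G1.

    G1 = [n² / ((n−1)(n−2))] · m3 / s³ with s the (n−1)-denominator sample
    standard deviation; requires n ≥ 3 and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("G1 needs at least 3 values")
    if np.isclose(x.var(), 0.0):
        raise ValueError("G1 undefined for zero variance")
    return float(stats.skew(x, bias=False))


def normality_test(values) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, P)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    if np.isclose(x.var(), 0.0):
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


@dataclass
class SizeDistributionDiagnostics:
    skewness_g1: float
    shapiro_w: float
    shapiro_p: float
    n: int


def size_distribution_diagnostics(log10_sizes) -> SizeDistributionDiagnostics:
    """Skewness and normality of a pooled log10 size sample."""
    x = np.asarray(log10_sizes, dtype=float)
    w, p = normality_test(x)
    return SizeDistributionDiagnostics(
        skewness_g1=skewness_g1(x), shapiro_w=w, shapiro_p=p, n=int(x.size)
    )
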