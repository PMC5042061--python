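"""Run configuration for the shell-size analysis pipeline.

All tunables that the analysis depends on live in :class:`RunConfig` so a
run is fully described by (input tables, config, seed).  Configs round-trip
through YAML for the command-line interface.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Settings controlling filtering, regression and resampling.

    Parameters
    ----------
    resample_fraction : float
        Fraction of each lake's fauna drawn (without replacement) per
        resampling replicate. Default 0.25.
    resample_reps : int
        Number of resampling replicates. Default 1000.
    seed : int, optional
        Master seed for every stochastic step; recorded in the run log.
    min_species_per_lake : int
        Lakes with fewer measured species are excluded. Default 4.
    min_subsample : int
        Floor on the per-lake subsample size (ranges need two species).
    family_min_lakes : int
        A family must occur in at least this many lakes to enter the
        family-level battery ("more than five lakes" -> 6).
    age_uncertainty_max : float
        Occurrences dated less precisely than this (Myr) are dropped from
        longevity and lake-age analyses. Default 3.0.
    exclude_caspian : bool
        Re-run the area regressions without the Caspian fauna.
    caspian_lake_id : str
        Which lake the exclusion toggle removes.
    s_range_mode : str
        "raw_difference" (log10(max - min), default) or "log_difference"
        (log10 max - log10 min).
    s_mean_mode : str
        "arithmetic" (log10 of the raw arithmetic mean, default) or
        "geometric" (mean of log10 sizes).
    resampling_mode : str
        "literal" (P = share of resampled slopes strictly greater than the
        observed slope, default) or "two_sided_magnitude".
    incidence_source : str
        "measured" builds family incidence from size-bearing species only
        (default); "all" uses every record.
    """

    resample_fraction: float = 0.25
    resample_reps: int = 1000
    seed: Optional[int] = None
    min_species_per_lake: int = 4
    min_subsample: int = 2
    family_min_lakes: int = 6
    age_uncertainty_max: float = 3.0
    exclude_caspian: bool = False
    caspian_lake_id: str = "Caspian Sea"
    s_range_mode: str = "raw_difference"
    s_mean_mode: str = "arithmetic"
    resampling_mode: str = "literal"
    incidence_source: str = "measured"
    log10_predictors: tuple = field(
        default=("area", "distance", "n_species"), repr=False
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.resample_fraction <= 1.0:
            raise ValueError("resample_fraction must be in (0, 1]")
        if self.resample_reps < 1:
            raise ValueError("resample_reps must be >= 1")
        if self.min_subsample < 1:
            raise ValueError("min_subsample must be >= 1")
        if self.s_range_mode not in ("raw_difference", "log_difference"):
            raise ValueError(f"unknown s_range_mode {self.s_range_mode!r}")
        if self.s_mean_mode not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown s_mean_mode {self.s_mean_mode!r}")
        if self.resampling_mode not in ("literal", "two_sided_magnitude"):
            raise ValueError(f"unknown resampling_mode {self.resampling_mode!r}")
        if self.incidence_source not in ("measured", "all"):
            raise ValueError(f"unknown incidence_source {self.incidence_source!r}")
        self.log10_predictors = tuple(self.log10_predictors)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["log10_predictors"] = list(self.log10_predictors)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML file into a :class:`RunConfig`, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
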