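"""Species and lake table ingestion, validation and inclusion filters.

The two inputs are plain CSV (UTF-8, comma separated, "." decimal, header
row required):

* a **species table** with one row per species occurrence in a lake —
  columns ``species_id, lake_id, family, height, width, endemic`` plus
  optional ``first_age, last_age, age_uncertainty, lineage_id, clade_rank,
  horizon``;
* a **lake table** with one row per lake — columns ``lake_id, latitude,
  longitude, area, duration, pct_endemism, distance, n_species`` plus
  optional ``age_top, age_base``.

Heights and widths are in mm, areas in km², distances in km, ages in Ma
before present (larger = older), durations in Myr, endemism in percent.

Records with a missing height or width are retained in the data model with
``size_missing = True`` and excluded from every analysis; downstream
species richness always means the number of *measured* species in a lake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "SchemaError",
    "RowError",
    "ExclusionReport",
    "SPECIES_REQUIRED",
    "SPECIES_OPTIONAL",
    "LAKE_REQUIRED",
    "load_species_table",
    "load_lake_table",
    "write_species_table",
    "apply_inclusion_filters",
    "exclusion_report_percentage",
    "measured_richness",
]

SPECIES_REQUIRED = ["species_id", "lake_id", "family", "height", "width", "endemic"]
SPECIES_OPTIONAL = [
    "first_age",
    "last_age",
    "age_uncertainty",
    "lineage_id",
    "clade_rank",
    "horizon",
]
SPECIES_NUMERIC = ["height", "width", "first_age", "last_age", "age_uncertainty", "clade_rank"]

LAKE_REQUIRED = [
    "lake_id",
    "latitude",
    "longitude",
    "area",
    "duration",
    "pct_endemism",
    "distance",
    "n_species",
]
LAKE_OPTIONAL = ["age_top", "age_base", "mean_beta"]
LAKE_NUMERIC = LAKE_REQUIRED[1:] + LAKE_OPTIONAL

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


class SchemaError(ValueError):
    """A required column is absent or the file is structurally unusable."""


class RowError(ValueError):
    """One or more data rows failed validation; carries (line, message) pairs."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"{len(problems)} malformed row(s): {lines}{more}")


@dataclass
class ExclusionReport:
    """Counts of what the inclusion filters removed and why."""

    n_species_in: int = 0
    n_species_no_size: int = 0
    n_species_in_dropped_lakes: int = 0
    n_species_out: int = 0
    n_lakes_in: int = 0
    n_lakes_too_small: int = 0
    n_lakes_out: int = 0
    dropped_lakes: list = field(default_factory=list)

    @property
    def pct_no_size(self) -> float:
        return exclusion_report_percentage(self.n_species_no_size, self.n_species_in)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["pct_no_size"] = round(self.pct_no_size, 1)
        return d


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str], problems: list) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        raw = df[col].astype("string").str.strip()
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & (raw != "") & coerced.isna()
        for idx in df.index[bad]:
            problems.append((int(idx) + 2, f"malformed numeric value {raw[idx]!r} in {col!r}"))
        df[col] = coerced


def _parse_bool(series: pd.Series, column: str, problems: list) -> pd.Series:
    raw = series.astype("string").str.strip().str.lower()
    out = pd.Series(False, index=series.index)
    for idx, val in raw.items():
        v = "" if pd.isna(val) else val
        if v in _TRUE:
            out[idx] = True
        elif v in _FALSE:
            out[idx] = False
        else:
            problems.append((int(idx) + 2, f"malformed boolean {val!r} in {column!r}"))
    return out


def load_species_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a species table.

    Returns a DataFrame with all input columns plus a boolean
    ``size_missing`` flag; rows without both height and width are flagged,
    never silently dropped.

    Raises
    ------
    SchemaError
        if a required column is missing.
    RowError
        if any cell fails to parse or violates a domain invariant; the
        error lists 1-based file line numbers.
    """
    df = pd.read_csv(path, dtype="string")
    missing = [c for c in SPECIES_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"species table {path} missing required column(s): {missing}")

    problems: list[tuple[int, str]] = []
    _coerce_numeric(df, SPECIES_NUMERIC, problems)
    df["endemic"] = _parse_bool(df["endemic"], "endemic", problems)

    for col in ("height", "width"):
        bad = df[col].notna() & (df[col] <= 0)
        for idx in df.index[bad]:
            problems.append((int(idx) + 2, f"{col} must be > 0, got {df[col][idx]}"))
    if "first_age" in df.columns and "last_age" in df.columns:
        both = df["first_age"].notna() & df["last_age"].notna()
        bad = both & (df["first_age"] < df["last_age"])
        for idx in df.index[bad]:
            problems.append(
                (int(idx) + 2, "first_age < last_age (ages are Ma before present)")
            )
    if problems:
        raise RowError(sorted(problems))

    for col in SPECIES_OPTIONAL:
        if col not in df.columns:
            df[col] = pd.NA if col in ("lineage_id", "horizon") else np.nan
    df["size_missing"] = df["height"].isna() | df["width"].isna()
    return df


def load_lake_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a lake table (one row per lake)."""
    df = pd.read_csv(path, dtype="string")
    missing = [c for c in LAKE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"lake table {path} missing required column(s): {missing}")

    problems: list[tuple[int, str]] = []
    _coerce_numeric(df, LAKE_NUMERIC, problems)
    for col in ("area", "distance", "duration"):
        bad = df[col].notna() & (df[col] <= 0)
        for idx in df.index[bad]:
            problems.append((int(idx) + 2, f"{col} must be > 0 (log-transformable)"))
    bad = df["pct_endemism"].notna() & ~df["pct_endemism"].between(0, 100)
    for idx in df.index[bad]:
        problems.append((int(idx) + 2, "pct_endemism must be in [0, 100]"))
    if df["lake_id"].duplicated().any():
        dupes = df["lake_id"][df["lake_id"].duplicated()].tolist()
        raise SchemaError(f"duplicate lake_id rows: {dupes}")
    if problems:
        raise RowError(sorted(problems))
    return df


def write_species_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a species table so that a re-read round-trips all fields."""
    out = df.drop(columns=["size_missing"], errors="ignore")
    out.to_csv(path, index=False)


def exclusion_report_percentage(n_excluded: int, n_total: int) -> float:
    """Percentage of records excluded, 100 * n_excluded / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_excluded <= n_total:
        raise ValueError("need 0 <= n_excluded <= n_total")
    return 100.0 * n_excluded / n_total


def measured_richness(species: pd.DataFrame) -> pd.Series:
    """Number of measured (size-bearing) species per lake.

    This is the richness used by every downstream analysis; the lake
    table's ``n_species`` totals are carried as metadata only.
    """
    ok = species[~species["size_missing"]]
    return ok.groupby("lake_id").size().rename("n_measured")


def apply_inclusion_filters(
    species: pd.DataFrame,
    lakes: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionReport]:
    """Apply the study's inclusion rules.

    Species without size information are removed (and counted); lakes
    retaining fewer measured species than ``config.min_species_per_lake``
    are removed together with their species. Filtering is idempotent.
    """
    config = config or RunConfig()
    report = ExclusionReport(n_species_in=len(species), n_lakes_in=len(lakes))

    sized = species[~species["size_missing"]].copy()
    report.n_species_no_size = len(species) - len(sized)

    counts = sized.groupby("lake_id").size()
    keep_ids = set(counts[counts >= config.min_species_per_lake].index)
    keep_ids &= set(lakes["lake_id"])
    if config.exclude_caspian:
        keep_ids.discard(config.caspian_lake_id)

    lakes_out = lakes[lakes["lake_id"].isin(keep_ids)].copy()
    report.dropped_lakes = sorted(set(lakes["lake_id"]) - keep_ids)
    report.n_lakes_too_small = len(lakes) - len(lakes_out)
    report.n_lakes_out = len(lakes_out)
    if lakes_out.empty:
        raise ValueError(
            "all lakes excluded by the inclusion filters "
            f"(min {config.min_species_per_lake} measured species per lake)"
        )

    species_out = sized[sized["lake_id"].isin(keep_ids)].copy()
    report.n_species_in_dropped_lakes = len(sized) - len(species_out)
    report.n_species_out = len(species_out)
    return species_out, lakes_out, report
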