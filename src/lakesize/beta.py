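"""Family-composition beta diversity between lake faunas.

Differences in family composition are scored with the incidence-based
Jaccard dissimilarity β_jac = (b + c) / (a + b + c), where *a* is the
number of families shared by two lakes and *b*, *c* the numbers unique to
each.  The full pairwise matrix is summarised into one predictor per lake
by averaging each lake's off-diagonal row — its mean family-level
difference from all other lakes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "family_incidence",
    "jaccard_dissimilarity",
    "beta_matrix",
    "mean_beta_per_lake",
]


def family_incidence(
    species: pd.DataFrame, on_missing_family: str = "drop"
) -> pd.DataFrame:
    """Lake × family presence/absence (0/1) matrix from a species table.

    A cell is 1 iff at least one measured species of that family occurs in
    that lake (duplicates are idempotent). Records without a family label
    are dropped (``on_missing_family="drop"``) or fatal (``"error"``).
    """
    df = species
    if "size_missing" in df.columns:
        df = df[~df["size_missing"]]
    missing = df["family"].isna() | (df["family"].astype("string").str.strip() == "")
    if missing.any():
        if on_missing_family == "error":
            raise ValueError(f"{int(missing.sum())} species record(s) lack a family label")
        df = df[~missing]
    inc = (
        pd.crosstab(df["lake_id"], df["family"]).clip(upper=1).astype(int)
    )
    inc.index.name = "lake_id"
    inc.columns.name = "family"
    return inc


def jaccard_dissimilarity(families_a, families_b) -> float:
    """β_jac between two family sets: (b + c) / (a + b + c).

    0 iff the sets are identical, 1 iff disjoint; undefined (error) when
    both are empty.
    """
    a, b = set(families_a), set(families_b)
    union = a | b
    if not union:
        raise ValueError("beta-Jaccard undefined for two empty faunas")
    return len(a ^ b) / len(union)


def beta_matrix(incidence: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric matrix of pairwise β_jac values between lakes."""
    x = incidence.to_numpy(dtype=bool)
    if (~x.any(axis=1)).any():
        empty = incidence.index[~x.any(axis=1)].tolist()
        raise ValueError(f"lake(s) with no families present: {empty}")
    mat = squareform(pdist(x, metric="jaccard"))
    return pd.DataFrame(mat, index=incidence.index, columns=incidence.index)


def mean_beta_per_lake(beta: pd.DataFrame) -> pd.Series:
    """Per-lake mean of the off-diagonal β_jac values (the predictor)."""
    n = beta.shape[0]
    if n < 2:
        raise ValueError("need at least two lakes to average pairwise dissimilarities")
    vals = beta.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T) or not np.allclose(np.diag(vals), 0.0):
        raise ValueError("beta matrix must be symmetric with zero diagonal")
    means = (vals.sum(axis=1)) / (n - 1)
    return pd.Series(means, index=beta.index, name="mean_beta")
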