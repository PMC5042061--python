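"""Bundled reference data.

``study_lakes`` returns the physiographic and faunal summary of the 23
Miocene-to-recent long-lived European lakes that motivated this package:
centroid coordinates, surface area (km²), environment duration (Myr),
percent single-lake endemism, distance to the closest coeval lake (km),
species count over the lake's entire duration, and the per-lake mean
family-level Jaccard dissimilarity.  It is the canonical small input for
desk-scale checks (for example the positive correlation between endemism
and log10 species richness).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["study_lakes"]


def study_lakes() -> pd.DataFrame:
    """The 23-lake summary table (one row per lake)."""
    with resources.files("lakesize.data").joinpath("study_lakes.csv").open() as fh:
        return pd.read_csv(fh)
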