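"""Bundled example tables.

``load_pathology_counts`` returns the per-type case counts of the breast
study cohort this toolkit's statistics module targets (one row per
pathology type, benign or malignant); ``pathology_totals`` sums them per
category. These are bookkeeping inputs for the statistics examples, not
simulation parameters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_pathology_counts", "pathology_totals"]


def load_pathology_counts() -> pd.DataFrame:
    """Per-pathology-type case counts (columns: category, pathology_type, n_cases)."""
    with resources.files("shearwave.data").joinpath("pathology_counts.csv").open() as fh:
        return pd.read_csv(fh)


def pathology_totals() -> dict:
    """Total case counts per category, summed from the per-type table."""
    df = load_pathology_counts()
    totals = df.groupby("category")["n_cases"].sum()
    return {str(k): int(v) for k, v in totals.items()}
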