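"""Grouped median/IQR summaries of extracted feature tables.

Quartiles use the inclusive linear-interpolation convention (spreadsheet
QUARTILE semantics, quantile type 7), matching how clinical summary tables
of this kind are usually prepared.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


class MedianIQR(NamedTuple):
    median: float
    q1: float
    q3: float
    iqr: float


def median_iqr(values) -> MedianIQR:
    """Median, inclusive-interpolated quartiles and IQR of a non-empty list."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires a non-empty list of values")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    return MedianIQR(float(med), float(q1), float(q3), float(q3 - q1))


def summarize(features: pd.DataFrame, feature: str,
              by: Sequence[str]) -> pd.DataFrame:
    """One median/IQR row per group of a feature table.

    ``feature`` names a numeric column (e.g. ``"e_static_kpa"``); ``by`` is
    the grouping key (e.g. ``["pressure", "label"]``).  Rows are ordered
    deterministically by the group key.  Cell counts over any partition sum
    to the total number of contributing rows.
    """
    if feature not in features.columns:
        raise ValueError(f"unknown feature column {feature!r}")
    missing = [k for k in by if k not in features.columns]
    if missing:
        raise ValueError(f"grouping keys not present: {missing}")

    rows = []
    for key, grp in features.groupby(list(by), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        stats = median_iqr(grp[feature].to_numpy())
        rows.append({**dict(zip(by, key)), "n": len(grp),
                     "median": stats.median, "q1": stats.q1,
                     "q3": stats.q3, "iqr": stats.iqr})
    return pd.DataFrame(rows, columns=[*by, "n", "median", "q1", "q3", "iqr"])


def label_table(features: pd.DataFrame, feature: str,
                by: Sequence[str], label_col: str = "label") -> pd.DataFrame:
    """Wide summary with C and NC columns side by side, one row per group."""
    long = summarize(features, feature, [*by, label_col])
    wide = long.pivot(index=list(by), columns=label_col,
                      values=["n", "median", "iqr"])
    wide.columns = [f"{stat}_{lab}" for stat, lab in wide.columns]
    order = [c for lab in ("C", "NC")
             for c in (f"n_{lab}", f"median_{lab}", f"iqr_{lab}")
             if c in wide.columns]
    return wide[order].reset_index()
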