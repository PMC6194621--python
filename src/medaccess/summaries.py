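"""Basket medians and product-specific year-on-year change statistics.

Shared by the availability and pricing modules: a basket summary is the
median over drugs of a per-drug metric, and the product-specific delta for a
pair of adjacent years is the median over drugs of each drug's change —
drugs missing in either year are excluded (and counted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["basket_median", "product_specific_delta"]


def basket_median(values) -> float:
    """Median of per-drug values; even counts use the mean of the central pair."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty basket")
    return float(np.median(arr))


def product_specific_delta(
    values: pd.DataFrame,
    year_pair: tuple[int, int],
    drug_col: str = "drug_id",
    year_col: str = "year",
    value_col: str = "value",
) -> tuple[float, int]:
    """Median over drugs of ``value[y1] - value[y0]`` for adjacent years.

    ``values`` is tidy (one row per drug x year).  Returns ``(delta,
    n_excluded)`` where ``n_excluded`` counts drugs absent from either year.
    Raises if no drug is present in both years.
    """
    y0, y1 = year_pair
    wide = values.pivot_table(
        index=drug_col, columns=year_col, values=value_col, aggfunc="first"
    )
    for y in (y0, y1):
        if y not in wide.columns:
            wide[y] = np.nan
    diffs = (wide[y1] - wide[y0]).dropna()
    if diffs.empty:
        raise ValueError(f"no drug observed in both {y0} and {y1}")
    n_excluded = len(wide) - len(diffs)
    return float(np.median(diffs.to_numpy())), n_excluded
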