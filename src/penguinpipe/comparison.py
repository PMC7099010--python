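"""Cross-method validation of per-image counts.

Three independent counting methods are compared per image: expert
gold-standard annotation (GS), filtered citizen-science consensus
clicks (CS), and density-map summation (CV).  For a pair of count
columns the signed difference is *first − second*, so a positive value
means the second method under-estimated relative to the first.  Pair
summaries report the mean and standard deviation of the absolute
differences (signs are irrelevant to the size of the disagreement),
the proportion of images agreeing to within one penguin, and the
tallies of over-, under- and exactly-matching estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: The six published column pairs, keyed by a short name.
PAIRS: dict[str, tuple[str, str]] = {
    "GS_combined_vs_CV_rounded": ("GS_combined", "CV_rounded"),
    "GS_adults_vs_CV_rounded": ("GS_adults", "CV_rounded"),
    "CS_combined_vs_CV_rounded": ("CS_combined", "CV_rounded"),
    "CS_adults_vs_CV_rounded": ("CS_adults", "CV_rounded"),
    "GS_combined_vs_CS_combined": ("GS_combined", "CS_combined"),
    "GS_adults_vs_CS_adults": ("GS_adults", "CS_adults"),
}


@dataclass(frozen=True)
class PairSummary:
    """Agreement statistics between two per-image count series."""

    pair: str
    n: int
    mean_abs_diff: float
    sd_abs_diff: float
    prop_within_one: float
    n_over: int
    n_under: int
    n_equal: int


def signed_diff(first, second):
    """first − second; positive ⇒ the second method under-estimates.

    Accepts scalars or aligned vectors; missing inputs yield missing
    outputs.
    """
    if np.ndim(first) == 0 and np.ndim(second) == 0:
        if pd.isna(first) or pd.isna(second):
            return float("nan")
        return first - second
    return pd.Series(first).astype("Float64") - pd.Series(second).astype("Float64")


def summarize_pair(records: pd.DataFrame, pair: str | tuple[str, str],
                   signed_sd: bool = False) -> PairSummary:
    """Summarise the per-image differences for one column pair.

    ``pair`` is either a key of :data:`PAIRS` or an explicit
    ``(first_column, second_column)`` tuple.  Rows with a missing count
    in either column are dropped (logged).  ``signed_sd=True`` reports
    the SD of the signed rather than absolute differences, as a
    sensitivity check.
    """
    if isinstance(pair, str):
        if pair not in PAIRS:
            raise ValidationError(f"unknown comparison pair {pair!r}; known: {sorted(PAIRS)}")
        first_col, second_col = PAIRS[pair]
        name = pair
    else:
        first_col, second_col = pair
        name = f"{first_col}_vs_{second_col}"
    for col in (first_col, second_col):
        if col not in records.columns:
            raise ValidationError(f"comparison table lacks column {col!r}")
    sub = records[[first_col, second_col]].dropna()
    dropped = len(records) - len(sub)
    if dropped:
        logger.info("pair %s: dropped %d row(s) with missing counts", name, dropped)
    if len(sub) == 0:
        raise ValidationError(f"pair {name}: no rows with both counts present")

    diffs = sub[first_col].astype(float).to_numpy() - sub[second_col].astype(float).to_numpy()
    abs_diffs = np.abs(diffs)
    sd_basis = diffs if signed_sd else abs_diffs
    n = len(diffs)
    return PairSummary(
        pair=name,
        n=n,
        mean_abs_diff=float(abs_diffs.mean()),
        sd_abs_diff=float(np.std(sd_basis, ddof=1)) if n > 1 else 0.0,
        prop_within_one=float((abs_diffs <= 1).mean()),
        n_over=int((diffs < 0).sum()),
        n_under=int((diffs > 0).sum()),
        n_equal=int((diffs == 0).sum()),
    )


def add_comparison_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Append signed and absolute difference columns for all six pairs."""
    out = records.copy()
    for name, (first_col, second_col) in PAIRS.items():
        d = signed_diff(out[first_col], out[second_col])
        out[name] = d
        out[name + "_abs"] = d.abs()
    return out


def summary_table(records: pd.DataFrame, signed_sd: bool = False) -> pd.DataFrame:
    """One-row-per-pair summary of all six published comparisons."""
    rows = [summarize_pair(records, name, signed_sd=signed_sd).__dict__ for name in PAIRS]
    return pd.DataFrame(rows)
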