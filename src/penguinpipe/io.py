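"""Reading and writing the pipeline's tabular formats.

All tables are comma-separated UTF-8 files with a header row and the
literal ``NA`` as the sole missing-value marker (the convention of the
published R-written archives).  Tables are carried in memory as pandas
DataFrames; the column sets below define each file kind.  Datetimes are
kept as the verbatim ``YYYY:MM:DD HH:MM:SS`` strings they arrive in —
cameras record local time with no zone — and are parsed only where
ordering is needed.

Coordinates are real-valued pixels in a 0-based frame whose origin is the
top-left corner of the photograph; y increases downward.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

NA = "NA"

MANIFEST_COLUMNS = [
    "name", "datetime", "zooniverse_id", "path", "classification_count",
    "state", "temperature_f", "lunar_phase", "URL",
]
RAW_CLICK_COLUMNS = ["name", "volunteer", "x", "y", "label"]
CONSENSUS_COLUMNS = [
    "name", "probability_of_adult", "probability_of_chick", "probability_of_egg",
    "num_markings", "x_centre", "y_centre",
]
KRAKEN_COLUMNS = CONSENSUS_COLUMNS + ["datetime", "temperature_f", "lunar_phase", "URL"]
NARWHAL_COLUMNS = [
    "imageid", "nadults", "nchicks", "neggs",
    "adultndout", "adultsdndout", "chickndout", "chicksdndout",
    "chick2ndout", "chicksd2ndout", "meanchangeadult", "meanchangechick",
    "tempf", "tempc", "datetime", "lunar_phase", "URL",
]
COMPARISON_COLUMNS = [
    "imageid", "datetime", "GS_adults", "GS_combined",
    "CS_adults", "CS_combined", "CV_rounded",
]
PENGBOT_COUNT_COLUMNS = ["imageid", "raw_count", "count"]

STATES = frozenset({"complete", "incomplete"})
LUNAR_PHASES = frozenset(
    {"full", "new", "newcres", "firstq", "waxinggib", "waninggib", "lastq", "oldcres"}
)
CLICK_LABELS = frozenset({"adult", "chick", "egg", "other"})

DATETIME_FORMAT = "%Y:%m:%d %H:%M:%S"

# Columns coerced to pandas nullable integers so that "NA" survives a
# round trip without silently floating integer counts.
_INT_COLUMNS = {
    "classification_count", "num_markings", "nadults", "nchicks", "neggs",
    "GS_adults", "GS_combined", "CS_adults", "CS_combined", "CV_rounded", "count",
}


def _read_csv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False, dtype="object")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(required)}, found {list(df.columns)}"
        )
    for col in df.columns:
        if col in _INT_COLUMNS:
            df[col] = pd.to_numeric(df[col]).astype("Int64")
        elif col in {"x", "y", "x_centre", "y_centre", "temperature_f", "tempf",
                     "tempc", "probability_of_adult", "probability_of_chick",
                     "probability_of_egg", "raw_count",
                     "adultndout", "adultsdndout", "chickndout", "chicksdndout",
                     "chick2ndout", "chicksd2ndout", "meanchangeadult",
                     "meanchangechick"}:
            df[col] = pd.to_numeric(df[col]).astype(float)
    return df


def _check_enum(df: pd.DataFrame, column: str, allowed: frozenset, path) -> None:
    present = df[column].notna()
    bad = present & ~df[column].isin(allowed)
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(
            f"{path}: row {row + 1}: invalid {column} value "
            f"{df.loc[bad.idxmax(), column]!r}; allowed: {sorted(allowed)}"
        )


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-image metadata manifest.

    Validates the completion state against {complete, incomplete}, the
    lunar phase against the eight-phase vocabulary, and that every
    datetime parses as ``YYYY:MM:DD HH:MM:SS``.
    """
    df = _read_csv(path, MANIFEST_COLUMNS)
    _check_enum(df, "state", STATES, path)
    _check_enum(df, "lunar_phase", LUNAR_PHASES, path)
    try:
        pd.to_datetime(df["datetime"], format=DATETIME_FORMAT)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable datetime: {exc}") from exc
    return df


def read_raw_clicks(path: str | os.PathLike) -> pd.DataFrame:
    """Read one-row-per-click volunteer annotations."""
    df = _read_csv(path, RAW_CLICK_COLUMNS)
    _check_enum(df, "label", CLICK_LABELS, path)
    if (df["x"] < 0).any() or (df["y"] < 0).any():
        row = int((df["x"] < 0).idxmax() if (df["x"] < 0).any() else (df["y"] < 0).idxmax())
        raise ValidationError(f"{path}: row {row + 1}: negative click coordinate")
    return df


def read_consensus(path: str | os.PathLike) -> pd.DataFrame:
    """Read consensus clicks (also used for the filtered, metadata-merged files).

    A row whose probability, num_markings and centre fields are all ``NA``
    encodes "no penguins identified in this image"; partially missing
    annotation fields are rejected.
    """
    df = _read_csv(path, CONSENSUS_COLUMNS)
    ann = df[CONSENSUS_COLUMNS[1:]]
    n_missing = ann.isna().sum(axis=1)
    partial = (n_missing > 0) & (n_missing < ann.shape[1])
    if partial.any():
        row = int(partial.idxmax())
        raise ValidationError(
            f"{path}: row {row + 1}: annotation fields must be all present "
            "or all NA"
        )
    probs = df[["probability_of_adult", "probability_of_chick", "probability_of_egg"]]
    if ((probs < 0) | (probs > 1)).any().any():
        raise ValidationError(f"{path}: probability outside [0, 1]")
    if (df["num_markings"].dropna() < 1).any():
        raise ValidationError(f"{path}: num_markings must be >= 1 when present")
    return df


def read_narwhal(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-image metrics table (counts, neighbour distances, movement)."""
    return _read_csv(path, NARWHAL_COLUMNS)


def read_comparison(path: str | os.PathLike) -> pd.DataFrame:
    """Read a method-comparison count table (extra diff columns are kept)."""
    return _read_csv(path, COMPARISON_COLUMNS)


def read_pengbot_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a density-derived count table."""
    return _read_csv(path, PENGBOT_COUNT_COLUMNS)


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                columns: Sequence[str] | None = None) -> None:
    """Write a table as CSV with ``NA`` for missing values.

    ``columns`` selects and orders the output columns (defaults to the
    frame's own order); writing then re-reading then re-writing produces
    byte-identical files, which keeps archived outputs diffable.
    """
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"cannot write {path}: missing column(s) {missing}; "
                f"found {list(df.columns)}"
            )
        df = df[list(columns)]
    df.to_csv(path, index=False, na_rep=NA)
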