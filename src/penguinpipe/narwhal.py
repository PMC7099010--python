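"""Per-image counts, nearest-neighbour summaries and frame-to-frame movement.

From each image's filtered consensus clicks, this stage computes:

* counts of adults, chicks and eggs;
* the mean and standard deviation of each adult's distance to its
  nearest adult neighbour, each chick's distance to its nearest and to
  its *second*-nearest chick neighbour (brood-mates sit together on the
  nest — Pygoscelis penguins lay two eggs — so a chick's first
  neighbour is usually its sibling and the second-nearest distance is
  the informative whole-colony spacing signal);
* a tracking-free movement metric: for every adult (chick) in image
  *i*, the minimum distance to any adult (chick) position in image
  *i−1*, averaged over the image.  When displacements are small
  relative to inter-individual spacing, each individual's nearest
  previous-frame point is itself, so the average approximates the mean
  displacement.  This is identical to appending the individual's
  coordinate to the previous frame's set and taking its nearest
  neighbour there.

Distances are Euclidean, in pixels.  Standard deviations use the
sample (n−1) convention and are missing with fewer than two
contributing distances.  Camera temperatures arrive in °F and are
converted to °C.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .consensus import assign_classes
from .errors import ConfigError, ValidationError
from .imageref import frame_number
from .io import DATETIME_FORMAT, NARWHAL_COLUMNS


def mean_kth_nn(points: np.ndarray, k: int = 1) -> tuple[float, float]:
    """Mean and sample SD of each point's distance to its k-th nearest other point.

    Returns ``(nan, nan)`` when fewer than ``k + 1`` points exist, since
    no point then has a k-th neighbour.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < k + 1:
        return (math.nan, math.nan)
    tree = cKDTree(pts)
    # query includes the point itself at distance 0 in column 0
    dist, _ = tree.query(pts, k=k + 1)
    kth = dist[:, k]
    return (float(np.mean(kth)), float(np.std(kth, ddof=1)))


def mean_frame_movement(current: np.ndarray, previous: np.ndarray) -> float:
    """Mean over current-frame points of the distance to the nearest previous-frame point.

    Missing (NaN) when either frame's point set is empty.
    """
    cur = np.asarray(current, dtype=float).reshape(-1, 2)
    prev = np.asarray(previous, dtype=float).reshape(-1, 2)
    if len(cur) == 0 or len(prev) == 0:
        return math.nan
    tree = cKDTree(prev)
    dist, _ = tree.query(cur, k=1)
    return float(np.mean(dist))


def fahrenheit_to_celsius(tempf):
    """(°F − 32) × 5/9 at full precision; missing stays missing."""
    return (np.asarray(tempf, dtype=float) - 32.0) * 5.0 / 9.0 if np.ndim(tempf) else (
        math.nan if pd.isna(tempf) else (float(tempf) - 32.0) * 5.0 / 9.0
    )


def moving_average(values: Sequence[float], n: int) -> np.ndarray:
    """Trailing moving average that skips missing values.

    At index i the result is the mean of the most recent ``min(i+1, n)``
    non-missing observations among ``values[:i+1]``; missing when no
    observation has occurred yet.  Partial windows at the series start
    keep every frame's smoothed value defined.
    """
    if n < 1:
        raise ConfigError(f"moving-average window must be >= 1, got {n}")
    vals = np.asarray(values, dtype=float)
    out = np.full(len(vals), np.nan)
    window: list[float] = []
    for i, v in enumerate(vals):
        if not math.isnan(v):
            window.append(v)
            if len(window) > n:
                window.pop(0)
        if window:
            out[i] = sum(window) / len(window)
    return out


def _round6g(x: float) -> float:
    return float(f"{x:.6g}") if not math.isnan(x) else math.nan


def order_frames(kraken: pd.DataFrame) -> list[str]:
    """Image names in strict temporal order: datetime, then frame number.

    Raises if two images share a datetime and a frame number (no strict
    order exists).
    """
    meta = kraken[["name", "datetime"]].drop_duplicates("name")
    when = pd.to_datetime(meta["datetime"], format=DATETIME_FORMAT)
    frames = meta["name"].map(frame_number)
    order = pd.DataFrame({"name": meta["name"], "when": when, "frame": frames})
    order = order.sort_values(["when", "frame"], kind="stable")
    if order.duplicated(["when", "frame"]).any():
        raise ValidationError("frame series is not strictly ordered: duplicate (datetime, frame)")
    return list(order["name"])


def compute_narwhal(kraken: pd.DataFrame) -> pd.DataFrame:
    """Per-image metric table from a filtered, metadata-merged click table.

    One output row per image, in temporal order, including images with no
    retained clicks (counts 0, distance fields missing).  Movement fields
    are missing for the first frame and whenever either frame's class set
    is empty.
    """
    if len(kraken) == 0:
        raise ValidationError("cannot compute metrics from an empty table")
    names = order_frames(kraken)
    classes = assign_classes(kraken)
    meta = kraken.drop_duplicates("name").set_index("name")

    coords: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[str, dict[str, int]] = {}
    for name, group in kraken.groupby("name"):
        cls = classes.loc[group.index]
        per = {}
        cnt = {}
        for c in ("adult", "chick", "egg"):
            members = group.loc[(cls == c).fillna(False)]
            per[c] = members[["x_centre", "y_centre"]].to_numpy(dtype=float)
            cnt[c] = len(members)
        coords[name] = per
        counts[name] = cnt

    rows = []
    prev_name = None
    for name in names:
        adults = coords[name]["adult"]
        chicks = coords[name]["chick"]
        a_nn, a_sd = mean_kth_nn(adults, k=1)
        c_nn, c_sd = mean_kth_nn(chicks, k=1)
        c2_nn, c2_sd = mean_kth_nn(chicks, k=2)
        if prev_name is None:
            move_a = move_c = math.nan
        else:
            move_a = mean_frame_movement(adults, coords[prev_name]["adult"])
            move_c = mean_frame_movement(chicks, coords[prev_name]["chick"])
        tempf = meta.loc[name, "temperature_f"]
        tempf = float(tempf) if pd.notna(tempf) else math.nan
        rows.append({
            "imageid": name,
            "nadults": counts[name]["adult"],
            "nchicks": counts[name]["chick"],
            "neggs": counts[name]["egg"],
            "adultndout": a_nn, "adultsdndout": a_sd,
            "chickndout": c_nn, "chicksdndout": c_sd,
            "chick2ndout": c2_nn, "chicksd2ndout": c2_sd,
            "meanchangeadult": move_a, "meanchangechick": move_c,
            "tempf": tempf,
            "tempc": _round6g(fahrenheit_to_celsius(tempf)),
            "datetime": meta.loc[name, "datetime"],
            "lunar_phase": meta.loc[name, "lunar_phase"],
            "URL": meta.loc[name, "URL"],
        })
        prev_name = name
    out = pd.DataFrame(rows, columns=NARWHAL_COLUMNS)
    for c in ("nadults", "nchicks", "neggs"):
        out[c] = out[c].astype("Int64")
    return out


def write_narwhal(df: pd.DataFrame, path) -> None:
    from .io import write_table

    write_table(df, path, NARWHAL_COLUMNS)
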