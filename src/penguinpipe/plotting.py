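"""Cumulative summary plots of the per-image metric series.

Each plot shows three stacked panels of moving-average trends up to a
chosen frame: adult and chick counts (window 20), mean chick
second-nearest-neighbour distance (window 2), and adult frame-to-frame
movement (window 20).  Rendering the plot for every frame in turn and
stitching the images together yields an animation of the season; this
module emits the per-frame rasters only.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError
from .narwhal import moving_average


@dataclass(frozen=True)
class PlotWindows:
    """Moving-average window lengths for the three panels."""

    counts: int = 20
    chick2nd: int = 2
    movement: int = 20


DEFAULT_WINDOWS = PlotWindows()


def summary_series(records: pd.DataFrame, upto_frame: int | None = None,
                   windows: PlotWindows = DEFAULT_WINDOWS) -> dict[str, np.ndarray]:
    """Smoothed series feeding the three panels, truncated at ``upto_frame``.

    Returned keys: ``adults``, ``chicks`` (counts, window ``windows.counts``),
    ``chick2nd`` (window ``windows.chick2nd``), ``movement``
    (window ``windows.movement``), plus ``frame_index``.
    """
    if len(records) == 0:
        raise ValidationError("cannot plot an empty metric table")
    upto = len(records) if upto_frame is None else int(upto_frame)
    if not 1 <= upto <= len(records):
        raise ValidationError(f"upto_frame must be in 1..{len(records)}, got {upto}")
    sub = records.iloc[:upto]
    return {
        "frame_index": np.arange(1, upto + 1),
        "adults": moving_average(sub["nadults"].astype(float), windows.counts),
        "chicks": moving_average(sub["nchicks"].astype(float), windows.counts),
        "chick2nd": moving_average(sub["chick2ndout"], windows.chick2nd),
        "movement": moving_average(sub["meanchangeadult"], windows.movement),
    }


def plot_summary(records: pd.DataFrame, path, upto_frame: int | None = None,
                 windows: PlotWindows = DEFAULT_WINDOWS) -> str:
    """Write the three-panel summary raster for one frame; returns the path."""
    data = summary_series(records, upto_frame, windows)
    x = data["frame_index"]
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    axes[0].plot(x, data["adults"], color="tab:blue", label="adults")
    axes[0].plot(x, data["chicks"], color="tab:orange", label="chicks")
    axes[0].set_ylabel(f"count (moving avg, n={windows.counts})")
    axes[0].legend(loc="upper left")
    axes[1].plot(x, data["chick2nd"], color="tab:green")
    axes[1].set_ylabel(f"chick 2nd-NN dist / px (n={windows.chick2nd})")
    axes[2].plot(x, data["movement"], color="tab:red")
    axes[2].set_ylabel(f"adult movement / px (n={windows.movement})")
    axes[2].set_xlabel("image index")
    fig.suptitle(str(records.iloc[(upto_frame or len(records)) - 1]["imageid"]))
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return str(path)
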