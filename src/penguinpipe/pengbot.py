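"""Counting penguins from per-pixel density matrices.

A counting network assigns every pixel a non-negative "penguin
density" scaled so that the pixels making up one individual sum to
approximately one; the matrix total therefore estimates the number of
individuals (adults and chicks combined — density counting cannot
separate them).  Individuals straddling the image border contribute
only the in-frame part of their density mass, so border individuals
are systematically under-counted (the edge effect); this stage does not
compensate for that, faithfully reporting what the matrix contains.

Matrices arrive as MATLAB MAT-files in the archives, but delimited
text and NPY are accepted as equivalent carriers.  Row 0 of the matrix
is the top image row, matching the click coordinate frame.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io

from .errors import FormatError
from .io import PENGBOT_COUNT_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DensityMap:
    """A per-pixel density matrix for one image."""

    imageid: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise FormatError(f"density matrix must be 2-D and non-empty, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise FormatError("density matrix holds non-finite entries")


@dataclass(frozen=True)
class PengbotCount:
    """Estimated count for one image: matrix total and its rounded value."""

    imageid: str
    raw_count: float
    count: int


def _mat_candidates(path) -> dict[str, np.ndarray]:
    data = scipy.io.loadmat(path)
    out = {}
    for key, val in data.items():
        if key.startswith("__"):
            continue
        if isinstance(val, np.ndarray) and val.ndim == 2 and np.issubdtype(
                val.dtype, np.number) and val.size > 0:
            out[key] = val
    return out


def read_density(path: str | os.PathLike, format: str = "auto",
                 imageid: str | None = None, var_name: str | None = None) -> DensityMap:
    """Load a density matrix from a MAT-file, delimited text, or NPY file.

    For MAT-files the matrix variable is auto-detected when exactly one
    2-D numeric variable exists; otherwise ``var_name`` must name it.
    Negative entries (numerical noise from the network) are clamped to
    zero with a logged count rather than rejected.
    """
    path = os.fspath(path)
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        format = {"mat": "matfile", "npy": "npy"}.get(ext.lstrip("."), "delimited")
    if format == "matfile":
        candidates = _mat_candidates(path)
        if var_name is not None:
            if var_name not in candidates:
                raise FormatError(
                    f"{path}: no 2-D numeric variable named {var_name!r}; "
                    f"found {sorted(candidates)}"
                )
            values = candidates[var_name]
        elif len(candidates) == 1:
            values = next(iter(candidates.values()))
        elif not candidates:
            raise FormatError(f"{path}: no 2-D numeric variable found")
        else:
            raise FormatError(
                f"{path}: ambiguous MAT-file — {sorted(candidates)} are all 2-D "
                "numeric; pass var_name to choose"
            )
    elif format == "npy":
        values = np.load(path)
    elif format == "delimited":
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise FormatError(f"unknown density format {format!r}")

    values = np.asarray(values, dtype=float)
    negatives = int((values < 0).sum())
    if negatives:
        logger.warning("%s: clamped %d negative density entries to 0", path, negatives)
        values = np.clip(values, 0.0, None)
    if imageid is None:
        imageid = os.path.splitext(os.path.basename(path))[0]
    return DensityMap(imageid=imageid, values=values)


def round_half_away(x: float) -> int:
    """Round to the nearest integer with .5 ties going away from zero.

    Banker's rounding would surprise anyone tallying animals, so 2.5
    becomes 3, not 2.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def count_from_density(d: DensityMap) -> PengbotCount:
    """Estimate the image's count by summing all pixel densities."""
    raw = float(np.sum(d.values))
    return PengbotCount(imageid=d.imageid, raw_count=raw, count=round_half_away(raw))


def count_table(counts: list[PengbotCount]) -> pd.DataFrame:
    """Assemble per-image counts into the archive table layout."""
    df = pd.DataFrame(
        [(c.imageid, c.raw_count, c.count) for c in counts],
        columns=PENGBOT_COUNT_COLUMNS,
    )
    df["count"] = df["count"].astype("Int64")
    return df


def render_density(d: DensityMap, path, cmap: str = "viridis") -> str:
    """Write an 8-bit raster of the density matrix; returns the path.

    Brightness increases monotonically with density (perceptually
    uniform colormap), the maximum density mapping to the brightest
    level.  An all-zero map renders uniformly at the darkest level.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(d.values.max())
    plt.imsave(path, d.values, cmap=cmap, vmin=0.0, vmax=vmax if vmax > 0 else 1.0)
    return str(path)
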