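"""Aggregating volunteer clicks into per-individual consensus clicks.

Several volunteers (ten, when an image contains animals) each drop one
marker per individual they see, so the raw clicks for one image form
noisy clumps around the true individuals.  Agglomerative hierarchical
clustering with complete linkage on the Euclidean click coordinates,
cut at a fixed height, turns each clump into one *consensus click*:
the mean click position, the number of contributing volunteers
(``num_markings``), and per-class probabilities equal to the proportion
of member clicks carrying each label.

Complete linkage bounds the diameter of every cluster by the cut
height, which matches the goal of one consensus click per penguin;
the default cut of 20 px is of the order of an on-screen penguin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigError, ValidationError
from .io import CONSENSUS_COLUMNS

#: Classes a consensus click can be assigned to.
CLASSES = ("adult", "chick", "egg", "other")

#: In-memory consensus columns: the file schema plus the "other" share,
#: which is needed to recognise non-penguin clusters but is not archived.
CONSENSUS_FRAME_COLUMNS = CONSENSUS_COLUMNS + ["probability_of_other"]

DEFAULT_CUT_HEIGHT = 20.0


def _empty_consensus() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in CONSENSUS_FRAME_COLUMNS})
    df["name"] = df["name"].astype(object)
    df["num_markings"] = df["num_markings"].astype("Int64")
    return df


def cluster_clicks(clicks: pd.DataFrame, cut_height: float = DEFAULT_CUT_HEIGHT,
                   min_cluster: int = 1) -> pd.DataFrame:
    """Cluster one image's raw clicks into consensus clicks.

    Parameters
    ----------
    clicks
        Raw-click table (columns ``name, volunteer, x, y, label``) for a
        single image.  May be empty.
    cut_height
        Height (pixels) at which the complete-linkage dendrogram is cut;
        no two clicks further apart than this end up in one cluster.
    min_cluster
        Minimum member count for a cluster to be emitted.  The default 1
        keeps everything — reliability filtering happens downstream on
        ``num_markings`` thresholds, not here.

    Returns
    -------
    DataFrame with one row per cluster: ``name``, class probabilities,
    ``num_markings``, ``x_centre``, ``y_centre`` and the in-memory
    ``probability_of_other`` share.  Cluster centres are the arithmetic
    mean of all member clicks.  When one volunteer contributed several
    clicks to a cluster, only their click nearest the centre counts
    toward ``num_markings`` and the probabilities, so ``num_markings``
    reads as "number of volunteers marking this individual".
    """
    if cut_height <= 0:
        raise ConfigError(f"cut_height must be positive, got {cut_height}")
    if min_cluster < 1:
        raise ConfigError(f"min_cluster must be >= 1, got {min_cluster}")
    if len(clicks) == 0:
        return _empty_consensus()
    names = clicks["name"].unique()
    if len(names) > 1:
        raise ValidationError(
            f"cluster_clicks expects clicks from one image, got {sorted(names)}"
        )
    name = names[0]

    xy = clicks[["x", "y"]].to_numpy(dtype=float)
    if len(xy) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(xy), method="complete")
        labels = fcluster(z, t=cut_height, criterion="distance")

    rows = []
    for cid in np.unique(labels):
        member = clicks.loc[labels == cid]
        centre = member[["x", "y"]].mean()
        # one click per volunteer: keep each volunteer's click nearest the centre
        d2 = (member["x"] - centre["x"]) ** 2 + (member["y"] - centre["y"]) ** 2
        keep = d2.groupby(member["volunteer"]).idxmin()
        voters = member.loc[keep]
        n = len(voters)
        if n < min_cluster:
            continue
        shares = voters["label"].value_counts()
        rows.append({
            "name": name,
            "probability_of_adult": shares.get("adult", 0) / n,
            "probability_of_chick": shares.get("chick", 0) / n,
            "probability_of_egg": shares.get("egg", 0) / n,
            "num_markings": n,
            "x_centre": float(centre["x"]),
            "y_centre": float(centre["y"]),
            "probability_of_other": shares.get("other", 0) / n,
        })
    if not rows:
        return _empty_consensus()
    out = pd.DataFrame(rows, columns=CONSENSUS_FRAME_COLUMNS)
    out["num_markings"] = out["num_markings"].astype("Int64")
    return out


def cluster_all(clicks: pd.DataFrame, cut_height: float = DEFAULT_CUT_HEIGHT,
                min_cluster: int = 1) -> pd.DataFrame:
    """Cluster a multi-image raw-click table image by image."""
    if len(clicks) == 0:
        return _empty_consensus()
    parts = [
        cluster_clicks(group, cut_height=cut_height, min_cluster=min_cluster)
        for _, group in clicks.groupby("name", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def other_probability(row: pd.Series) -> float:
    """Share of member clicks labelled "other", recomputed if not stored."""
    if "probability_of_other" in row.index and pd.notna(row.get("probability_of_other")):
        return float(row["probability_of_other"])
    return 1.0 - float(
        row["probability_of_adult"] + row["probability_of_chick"] + row["probability_of_egg"]
    )


def assign_class(row: pd.Series) -> str:
    """Class of a consensus click: the label with maximal probability.

    Ties are broken deterministically in the order
    adult > chick > egg > other.

    Raises
    ------
    ValidationError
        If the probability fields are missing (a "no penguins" row has no
        class).
    """
    probs = [row.get("probability_of_adult"), row.get("probability_of_chick"),
             row.get("probability_of_egg")]
    if any(p is None or pd.isna(p) for p in probs):
        raise ValidationError("cannot assign a class: probability fields are missing")
    values = [float(probs[0]), float(probs[1]), float(probs[2]),
              max(other_probability(row), 0.0)]
    best = max(range(4), key=lambda i: (values[i], -i))
    return CLASSES[best]


def assign_classes(consensus: pd.DataFrame) -> pd.Series:
    """Vector of :func:`assign_class` over a consensus table.

    Rows encoding "no penguins" (missing probabilities) yield missing
    values instead of raising.
    """
    out = pd.Series(pd.NA, index=consensus.index, dtype="object")
    present = consensus["probability_of_adult"].notna()
    for idx in consensus.index[present]:
        out.loc[idx] = assign_class(consensus.loc[idx])
    return out
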