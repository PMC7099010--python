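import numpy as np
import pandas as pd
import pytest

from penguinpipe.io import MANIFEST_COLUMNS


def make_manifest(names, datetimes=None, temperature_f=35.0, lunar_phase="full"):
    """Minimal valid manifest frame for the given image names."""
    if datetimes is None:
        base = pd.Timestamp("2014:01:01 07:00:00".replace(":", "-", 2))
        datetimes = [(base + pd.Timedelta(hours=i)).strftime("%Y:%m:%d %H:%M:%S")
                     for i in range(len(names))]
    return pd.DataFrame({
        "name": list(names),
        "datetime": datetimes,
        "zooniverse_id": [f"APZ{i:07d}" for i in range(len(names))],
        "path": [f"DAMOa/{n}" for n in names],
        "classification_count": pd.array([10] * len(names), dtype="Int64"),
        "state": ["complete"] * len(names),
        "temperature_f": [temperature_f] * len(names),
        "lunar_phase": [lunar_phase] * len(names),
        "URL": [f"http://example.org/{n}.jpg" for n in names],
    })[MANIFEST_COLUMNS]


def make_consensus(names, classes, num_markings, x=None, y=None):
    """Consensus frame with pure-class probability vectors."""
    n = len(names)
    rows = []
    for i in range(n):
        p = {"probability_of_adult": 0.0, "probability_of_chick": 0.0,
             "probability_of_egg": 0.0, "probability_of_other": 0.0}
        p[f"probability_of_{classes[i]}"] = 1.0
        rows.append({
            "name": names[i], **p,
            "num_markings": num_markings[i],
            "x_centre": 100.0 + 50.0 * i if x is None else x[i],
            "y_centre": 200.0 if y is None else y[i],
        })
    df = pd.DataFrame(rows)
    df["num_markings"] = df["num_markings"].astype("Int64")
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20140901)
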