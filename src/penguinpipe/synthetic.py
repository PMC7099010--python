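"""Synthetic colonies, volunteer clicks and density matrices.

The generator emulates the statistical structure of the real archives
so that every pipeline stage can be exercised end to end without any
download:

* a **colony** of nests placed as a hard-core point process (nests are
  visibly spaced on the ground), photographed over a sequence of
  frames; adults sit at their nests with small frame-to-frame jitter,
  eggs appear on the nest until chicks emerge, and after crèche onset
  chicks abandon the nests for shared huddles — which is exactly the
  behaviour the chick second-nearest-neighbour metric is meant to
  expose;
* **volunteer clicks**: each of ~10 volunteers independently marks each
  individual with a class-dependent detection probability (chicks and
  especially eggs are often missed), isotropic Gaussian position
  noise, occasional uniform false positives, and a per-volunteer cap
  of 30 marks per image after which they move on;
* **density matrices**: one discrete Gaussian kernel per individual,
  normalised to unit mass before edge truncation, with the kernel
  footprint shrinking (and its peak growing) towards the top of the
  image where individuals appear smaller — so border-straddling
  individuals contribute less than one and the edge-effect undercount
  emerges naturally.

All randomness flows from one explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import MANIFEST_COLUMNS, RAW_CLICK_COLUMNS, write_table

SITE_CAMERA = "SIMUa"
DEPLOYMENT = "2020a"

LUNAR_CYCLE = ["new", "newcres", "firstq", "waxinggib",
               "full", "waninggib", "lastq", "oldcres"]


@dataclass(frozen=True)
class ColonyScenario:
    """Ground-truth colony layout and phenology schedule.

    Defaults describe a mid-sized Pygoscelis colony in the camera's
    field of view: a dozen nests at least 60 px apart in a
    1000×750 px frame, adults nearly always on the nest (presence
    0.95), two eggs per nest hatching into two chicks at frame 40,
    crèche onset at frame 70, and a 2 px per-frame position jitter
    (chicks roam more, 6 px, once crèched).
    """

    n_nests: int = 12
    frame_count: int = 100
    height: int = 750
    width: int = 1000
    nest_spacing: float = 60.0
    adult_presence: float = 0.95
    chick_emergence_frame: int = 40
    creche_onset_frame: int = 70
    chicks_per_nest: int = 2
    eggs_per_nest: int = 2
    movement_scale: float = 2.0
    creche_movement_scale: float = 6.0
    n_huddles: int = 3
    huddle_spread: float = 12.0
    edge_margin: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nest_spacing <= 0:
            raise ConfigError("nest_spacing must be positive")
        if not (0 <= self.chick_emergence_frame and 0 <= self.creche_onset_frame):
            raise ConfigError("phenology frames must be non-negative")
        if self.frame_count < 1 or self.n_nests < 1:
            raise ConfigError("frame_count and n_nests must be >= 1")


@dataclass(frozen=True)
class VolunteerModel:
    """Click-generation behaviour of the volunteer crowd."""

    volunteers_per_image: int = 10
    detection: dict = field(default_factory=lambda: {
        "adult": 0.95, "chick": 0.70, "egg": 0.40})
    click_noise_sd: float = 3.0
    false_positive_rate: float = 0.2  # Poisson mean per volunteer per image
    false_positive_mix: dict = field(default_factory=lambda: {
        "adult": 0.5, "chick": 0.3, "other": 0.2})
    click_cap: int = 30

    def __post_init__(self) -> None:
        for cls, p in self.detection.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"detection probability for {cls} outside [0, 1]")
        if self.click_cap < 0:
            raise ConfigError("click_cap must be >= 0")


@dataclass(frozen=True)
class PerspectiveModel:
    """Kernel scale as a function of image row.

    ``sigma(y)`` interpolates linearly from ``sigma_top`` at the top of
    the frame (distant, small individuals, sharp bright kernels) to
    ``sigma_bottom`` at the foreground.
    """

    sigma_top: float = 2.0
    sigma_bottom: float = 6.0

    def sigma(self, y: float, height: int) -> float:
        if self.sigma_top <= 0 or self.sigma_bottom <= 0:
            raise ConfigError("kernel sigmas must be positive")
        frac = np.clip(y / max(height - 1, 1), 0.0, 1.0)
        return self.sigma_top + (self.sigma_bottom - self.sigma_top) * frac


def image_name(frame: int) -> str:
    return f"{SITE_CAMERA}{DEPLOYMENT}_{frame:06d}"


def _place_nests(scenario: ColonyScenario, rng: np.random.Generator) -> np.ndarray:
    """Hard-core rejection sampling of nest sites; errors when infeasible."""
    m = scenario.edge_margin
    lo = np.array([m, m])
    hi = np.array([scenario.width - m, scenario.height - m])
    if (hi <= lo).any():
        raise ConfigError("edge margin leaves no room for nests")
    nests: list[np.ndarray] = []
    attempts = 0
    max_attempts = 10_000 * scenario.n_nests
    while len(nests) < scenario.n_nests:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"cannot place {scenario.n_nests} nests with spacing "
                f"{scenario.nest_spacing} in a {scenario.width}x{scenario.height} frame"
            )
        cand = lo + rng.random(2) * (hi - lo)
        if all(np.hypot(*(cand - n)) >= scenario.nest_spacing for n in nests):
            nests.append(cand)
    return np.array(nests)


def _place_huddles(scenario: ColonyScenario, nests: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Crèche huddle sites in open ground, clear of active nests."""
    m = scenario.edge_margin
    span = np.array([scenario.width - 2 * m, scenario.height - 2 * m])
    clearance = max(scenario.nest_spacing / 2, 2 * scenario.huddle_spread)
    huddles: list[np.ndarray] = []
    for _ in range(20_000):
        if len(huddles) == scenario.n_huddles:
            break
        cand = np.array([m, m]) + rng.random(2) * span
        if all(np.hypot(*(cand - n)) >= clearance for n in nests):
            huddles.append(cand)
    else:
        raise ConfigError("cannot place huddle sites clear of nests")
    return np.array(huddles)


def simulate_truth(scenario: ColonyScenario) -> pd.DataFrame:
    """Ground-truth individuals per frame.

    Returns a table with columns ``name, frame, class, x, y``; one row
    per visible individual.  Reproducible given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    nests = _place_nests(scenario, rng)
    # guard-phase chicks stand beside the parent, not on it, so their click
    # clumps stay separable from the adult's at the default cut height
    sib_offsets = np.array([[-16.0, 8.0], [16.0, -8.0], [0.0, 18.0], [-14.0, -14.0]])
    egg_offsets = np.array([[-4.0, 0.0], [4.0, 0.0], [0.0, 4.0], [0.0, -4.0]])
    huddles = _place_huddles(scenario, nests, rng)
    chick_huddle = rng.integers(0, scenario.n_huddles,
                                size=scenario.n_nests * scenario.chicks_per_nest)

    rows = []
    for frame in range(1, scenario.frame_count + 1):
        name = image_name(frame)

        def jitter(scale: float) -> np.ndarray:
            return rng.normal(0.0, scale, size=2) if scale > 0 else np.zeros(2)

        present = rng.random(scenario.n_nests) < scenario.adult_presence
        for i, nest in enumerate(nests):
            if present[i]:
                x, y = nest + jitter(scenario.movement_scale)
                rows.append((name, frame, "adult", x, y))
            if frame < scenario.chick_emergence_frame:
                # eggs sit under the incubating adult and are only visible
                # (hence clickable) when the adult is off the nest
                if not present[i]:
                    for e in range(scenario.eggs_per_nest):
                        x, y = nest + egg_offsets[e % len(egg_offsets)]
                        rows.append((name, frame, "egg", x, y))
            elif frame < scenario.creche_onset_frame:
                for c in range(scenario.chicks_per_nest):
                    x, y = (nest + sib_offsets[c % len(sib_offsets)]
                            + jitter(scenario.movement_scale))
                    rows.append((name, frame, "chick", x, y))
            else:
                for c in range(scenario.chicks_per_nest):
                    k = chick_huddle[i * scenario.chicks_per_nest + c]
                    spread = (rng.normal(0.0, scenario.huddle_spread, size=2)
                              if scenario.movement_scale > 0 or scenario.huddle_spread > 0
                              else np.zeros(2))
                    x, y = (huddles[k] + spread
                            + jitter(scenario.creche_movement_scale))
                    rows.append((name, frame, "chick", x, y))
    df = pd.DataFrame(rows, columns=["name", "frame", "class", "x", "y"])
    df["x"] = df["x"].clip(0.0, scenario.width - 1)
    df["y"] = df["y"].clip(0.0, scenario.height - 1)
    return df


def simulate_clicks(truth_frame: pd.DataFrame, vm: VolunteerModel,
                    seed: int, width: int, height: int) -> pd.DataFrame:
    """Volunteer clicks for one image's ground truth.

    Each volunteer independently detects each individual with the
    class detection probability, clicks at the true position plus
    isotropic Gaussian noise, and adds Poisson-distributed uniform
    false positives; their marks, in encounter order, are truncated at
    the click cap.
    """
    rng = np.random.default_rng(seed)
    names = truth_frame["name"].unique()
    name = names[0] if len(names) else image_name(0)
    truth_xy = truth_frame[["x", "y"]].to_numpy(dtype=float)
    truth_cls = truth_frame["class"].to_numpy()
    det = np.array([vm.detection.get(c, 0.0) for c in truth_cls])

    fp_labels = list(vm.false_positive_mix)
    fp_probs = np.array([vm.false_positive_mix[c] for c in fp_labels], dtype=float)
    fp_probs = fp_probs / fp_probs.sum() if fp_probs.sum() > 0 else fp_probs

    rows = []
    for v in range(vm.volunteers_per_image):
        token = f"vol{v:03d}"
        detected = rng.random(len(truth_xy)) < det
        marks_xy = truth_xy[detected]
        if vm.click_noise_sd > 0 and len(marks_xy):
            marks_xy = marks_xy + rng.normal(0.0, vm.click_noise_sd, size=marks_xy.shape)
        marks = [(x, y, c) for (x, y), c in zip(marks_xy, truth_cls[detected])]
        n_fp = rng.poisson(vm.false_positive_rate)
        for _ in range(n_fp):
            label = fp_labels[rng.choice(len(fp_labels), p=fp_probs)] if fp_labels else "other"
            marks.append((rng.random() * width, rng.random() * height, label))
        order = rng.permutation(len(marks))
        for idx in order[: vm.click_cap]:
            x, y, label = marks[idx]
            rows.append((name, token, max(x, 0.0), max(y, 0.0), label))
    return pd.DataFrame(rows, columns=RAW_CLICK_COLUMNS)


def simulate_all_clicks(truth: pd.DataFrame, vm: VolunteerModel, seed: int,
                        width: int, height: int) -> pd.DataFrame:
    """Clicks for every frame of a truth table (per-frame child seeds)."""
    parts = []
    for frame, group in truth.groupby("frame", sort=True):
        parts.append(simulate_clicks(group, vm, seed + int(frame), width, height))
    if not parts:
        return pd.DataFrame(columns=RAW_CLICK_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete isotropic Gaussian of unit total mass on its full footprint."""
    r = int(np.ceil(4 * sigma))
    ax = np.arange(-r, r + 1)
    g1 = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g1, g1)
    return k / k.sum()


def simulate_density(truth_frame: pd.DataFrame, height: int, width: int,
                     perspective: PerspectiveModel = PerspectiveModel()) -> np.ndarray:
    """Density matrix for one image: one unit-mass kernel per adult or chick.

    Kernels are normalised before edge truncation, so an individual
    centred on the border contributes roughly half its mass — the
    edge-effect undercount.  Eggs contribute nothing (density counting
    sees penguins, not eggs).
    """
    values = np.zeros((height, width))
    visible = truth_frame[truth_frame["class"].isin(["adult", "chick"])]
    for _, row in visible.iterrows():
        cx, cy = int(round(row["x"])), int(round(row["y"]))
        k = gaussian_kernel(perspective.sigma(row["y"], height))
        r = k.shape[0] // 2
        y0, y1 = cy - r, cy + r + 1
        x0, x1 = cx - r, cx + r + 1
        ky0, kx0 = max(0, -y0), max(0, -x0)
        ky1 = k.shape[0] - max(0, y1 - height)
        kx1 = k.shape[1] - max(0, x1 - width)
        if ky0 >= ky1 or kx0 >= kx1:
            continue
        values[max(0, y0):min(height, y1), max(0, x0):min(width, x1)] += k[ky0:ky1, kx0:kx1]
    return values


def simulate_manifest(scenario: ColonyScenario) -> pd.DataFrame:
    """Per-image metadata for a simulated deployment.

    Hourly captures within a 07:00–20:00 daily window starting
    1 December; temperatures around freezing; lunar phase stepping
    through the eight-phase cycle.
    """
    rng = np.random.default_rng(scenario.seed + 987_654)
    start = pd.Timestamp("2019-12-01 07:00:00")
    rows = []
    t = start
    for frame in range(1, scenario.frame_count + 1):
        name = image_name(frame)
        day = (t - start).days
        rows.append({
            "name": name,
            "datetime": t.strftime("%Y:%m:%d %H:%M:%S"),
            "zooniverse_id": f"APZ{frame:07d}",
            "path": f"{SITE_CAMERA}/{name}",
            "classification_count": 10,
            "state": "complete",
            "temperature_f": round(float(rng.normal(33.0, 6.0)), 1),
            "lunar_phase": LUNAR_CYCLE[(day // 4) % len(LUNAR_CYCLE)],
            "URL": f"http://example.org/thumb/{name}.jpg",
        })
        t = t + pd.Timedelta(hours=1)
        if t.hour > 20:
            t = t.normalize() + pd.Timedelta(days=1, hours=7)
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def simulate_dataset(scenario: ColonyScenario = ColonyScenario(),
                     vm: VolunteerModel = VolunteerModel()) -> dict[str, pd.DataFrame]:
    """Truth, raw clicks and manifest for a whole simulated deployment."""
    truth = simulate_truth(scenario)
    clicks = simulate_all_clicks(truth, vm, scenario.seed + 10_000,
                                 scenario.width, scenario.height)
    manifest = simulate_manifest(scenario)
    return {"truth": truth, "raw_clicks": clicks, "manifest": manifest}


def write_dataset(outdir: str | os.PathLike,
                  scenario: ColonyScenario = ColonyScenario(),
                  vm: VolunteerModel = VolunteerModel()) -> dict[str, str]:
    """Write a simulated deployment to disk in the pipeline's own formats.

    Emits ``truth.csv``, ``raw_clicks.csv`` and ``manifest.csv`` plus a
    ``metadata.json`` sidecar recording every generating parameter and
    the seed.  Returns the paths written.
    """
    os.makedirs(outdir, exist_ok=True)
    data = simulate_dataset(scenario, vm)
    paths = {}
    for key, columns in (("truth", None), ("raw_clicks", RAW_CLICK_COLUMNS),
                         ("manifest", MANIFEST_COLUMNS)):
        path = os.path.join(outdir, f"{key}.csv")
        write_table(data[key], path, columns)
        paths[key] = path
    meta_path = os.path.join(outdir, "metadata.json")
    with open(meta_path, "w") as fh:
        json.dump({
            "scenario": dataclasses.asdict(scenario),
            "volunteer_model": dataclasses.asdict(vm),
        }, fh, indent=2, sort_keys=True)
    paths["metadata"] = meta_path
    return paths
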