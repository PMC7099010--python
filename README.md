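# penguinpipe

Tools for turning dot-annotated time-lapse imagery of penguin colonies into
biologically meaningful metrics: per-image counts of adults, chicks and eggs,
nearest-neighbour summaries of colony spatial structure, a tracking-free
movement metric, and density-map counts — plus the statistics to
cross-validate counting methods against each other.

Remote time-lapse cameras photograph Antarctic and sub-Antarctic penguin
colonies roughly hourly. Two annotation routes produce usable data from the
images. In the **citizen-science route**, ~10 volunteers each mark every
individual in an image with an x/y click labelled *adult*, *chick* or *egg*
(or *other*); in the **computer-vision route**, a counting network emits a
per-pixel "penguin density" matrix whose entries for one individual sum to
approximately one. `penguinpipe` implements everything downstream of the
annotations:

1. **consensus** — agglomerative (complete-linkage) clustering of the raw
   clicks on one image into one *consensus click* per individual, with class
   probabilities equal to the proportion of volunteers choosing each label
   and `num_markings` = number of contributing volunteers;
2. **kraken** — reliability filtering (an adult consensus click needs more
   than 3 volunteer clicks, chicks and eggs more than 1) and a merge with
   per-image metadata (datetime, temperature, lunar phase);
3. **narwhal** — per-image counts; mean/SD distance of each adult to its
   nearest adult, of each chick to its nearest and *second*-nearest chick
   (Pygoscelis penguins lay two eggs, so a chick's first neighbour is usually
   its sibling); and mean frame-to-frame movement, computed as each
   individual's minimum distance to the previous image's same-class
   positions;
4. **pengbot** — density-matrix loading (MAT-file, delimited, NPY), counts by
   summing pixel densities, and density-map rendering;
5. **comparison** — agreement statistics (mean and SD of absolute count
   differences, proportion within one penguin, over/under-estimate tallies)
   between gold-standard, citizen-science and computer-vision counts;
6. **synthetic** — a seeded simulator of colonies (hard-core nest placement,
   egg→chick phenology, crèche huddling), volunteer clicks (per-class
   detection probabilities, Gaussian click noise, false positives, a
   30-marks-per-volunteer cap) and density matrices (unit-mass kernels that
   sharpen towards the image top, mimicking camera perspective), so the whole
   pipeline is testable without any field data.

## The metrics

For the adults \(\{p_j\}\) of image *i*, the nearest-neighbour summary is

```
adultndout(i) = mean_j  min_{j' ≠ j} ‖p_j − p_{j'}‖
```

with its sample SD; chicks get the analogous 1st- and 2nd-nearest versions.
Movement between consecutive images is

```
meanchange(i) = mean_j  min_{q ∈ frame i−1} ‖p_j − q‖
```

which equals each individual's displacement whenever it moved less than half
the inter-individual spacing (its nearest previous-frame point is then
itself). A density-map count is simply the matrix total, rounded half away
from zero.

## Worked example

```python
from penguinpipe import (ColonyScenario, DensityMap, build_kraken, cluster_all,
                         compute_narwhal, count_from_density, signed_diff,
                         simulate_dataset, simulate_density)

scenario = ColonyScenario(frame_count=20, seed=42)
data = simulate_dataset(scenario)                      # truth, clicks, manifest
consensus = cluster_all(data["raw_clicks"])            # volunteer clicks -> consensus
kraken = build_kraken(consensus, data["manifest"])     # filter + metadata merge
records = compute_narwhal(kraken)                      # counts + spatial metrics
print(records[["imageid", "nadults", "nchicks", "neggs",
               "adultndout", "meanchangeadult"]].head(5).to_string(index=False))

frame1 = data["truth"][data["truth"]["frame"] == 1]
density = simulate_density(frame1, scenario.height, scenario.width)
count = count_from_density(DensityMap("SIMUa2020a_000001", density))
print(f"density count: raw={count.raw_count:.3f} rounded={count.count}")
print("signed diff GS=15 vs CV=12:", signed_diff(15, 12))
```

prints

```
          imageid  nadults  nchicks  neggs  adultndout  meanchangeadult
SIMUa2020a_000001       12        0      0  162.514574              NaN
SIMUa2020a_000002       12        0      0  163.413354         2.748924
SIMUa2020a_000003       12        0      0  162.428198         3.336749
SIMUa2020a_000004       12        0      0  160.444540         4.172148
SIMUa2020a_000005       11        0      1  176.146804         3.138707
density count: raw=12.000 rounded=12
signed diff GS=15 vs CV=12: 3
```

All 12 simulated nests have their adult recovered in frames 1–4; in frame 5
one adult is off its nest, exposing an egg (`nadults` 11, `neggs` 1). The
~2–4 px `meanchangeadult` matches the simulator's per-frame position jitter,
and summing the density matrix recovers the 12 individuals exactly. The
first frame has no predecessor, so its movement is `NaN`. A positive signed
difference means the second method under-counted relative to the first.

The same pipeline is scriptable from a shell:

```
penguinpipe simulate  --outdir sim --frames 20 --seed 42
penguinpipe aggregate --clicks sim/raw_clicks.csv --out consensus.csv
penguinpipe kraken    --consensus consensus.csv --manifest sim/manifest.csv --out kraken.csv
penguinpipe narwhal   --kraken kraken.csv --manifest sim/manifest.csv --out narwhal.csv
penguinpipe plot      --narwhal narwhal.csv --out summary.png
```

Each command writes a `<output>.run.json` manifest (inputs, parameters,
version) next to its output, and identical inputs and seed reproduce outputs
byte for byte.

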