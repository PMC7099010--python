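# Methods

This note documents the models and procedures behind `penguinpipe`, the
choices made where the published file formats and narrative left the design
open, and what the synthetic-data tests do and do not demonstrate about real
camera data.

## Click aggregation (consensus)

Multiple volunteers annotate each image, each dropping at most one marker
per individual, so the raw clicks for an image form clumps around the true
individuals with substantial inter-volunteer scatter. We aggregate with
**agglomerative hierarchical clustering, complete linkage, Euclidean
distance, dendrogram cut at a fixed height** (default 20 px). Complete
linkage bounds every cluster's diameter by the cut height, which is the
right invariant for "one consensus click per penguin": two clumps merge only
if *all* their clicks are mutually within the cut, making the rule robust to
adjacent individuals. The cut default of 20 px is on the order of an
on-screen penguin in a typical deployment; it is configurable per run.
The archived aggregation used by the original project is an external script
whose linkage rule and threshold are not documented; ours is a documented
re-design, not a claimed replica.

Per cluster we report:

* centre = arithmetic mean of **all** member clicks (hence fractional
  pixels);
* `num_markings` = number of distinct volunteers contributing; when one
  volunteer placed several clicks in a cluster, only their click nearest the
  centre counts towards `num_markings` and the class probabilities, because
  downstream filtering reads `num_markings` as "number of independent
  volunteers";
* class probabilities = proportion of (deduplicated) member clicks with each
  label, computed over all four labels including "other"; the three penguin
  probabilities are archived and the "other" share is recoverable as their
  complement to 1.

Class assignment is argmax over {adult, chick, egg, other} with the
deterministic tie-break order adult > chick > egg > other. Ties are real at
small click counts (5 adult vs 5 chick clicks), so the order matters for
reproducibility; preferring adult reflects that adults are the easiest class
for volunteers to identify correctly.

## Reliability filtering (kraken)

A click of class *c* is retained iff `num_markings` **strictly exceeds** the
class threshold: defaults adult 3 (four or more volunteers), chick 1, egg 1
(two or more). The thresholds are exposed exactly as these strict
inequalities because that is how the published files describe them; they are
independent knobs, with eggs defaulting to the chick level since volunteers
often miss eggs and a lower bar is needed to keep them at all. Whether the
archived files thresholded on the argmax class or on per-class probability
mass is not documented; we use the argmax class, which makes filtering a
pure function of (class, `num_markings`) and hence monotone and idempotent —
both are property-tested.

The filtered clicks are left-joined with the image manifest. Manifest images
whose clicks were all filtered away (or that never had any) contribute one
row with all annotation fields missing, so every image appears and the frame
series downstream is gap-free. Metadata strings (datetime, URL) pass through
byte-for-byte.

## Counts, neighbour distances and movement (narwhal)

Frames are ordered by datetime, tie-broken by frame number; a series in
which two images share both admits no strict predecessor relation and is
rejected.

* **k-th nearest neighbour.** For each same-class point, the Euclidean
  distance to its k-th nearest other point (k=1 for adults and chicks, k=2
  additionally for chicks); we report the mean and the **sample** (n−1)
  standard deviation over points. The published files do not state the SD
  denominator; sample SD is the field convention. With fewer than k+1
  points the statistic is undefined and reported missing. Implementation
  uses a scipy cKD-tree; correctness is pinned to an all-pairs brute-force
  oracle at 1e-9.
* **Movement.** For each point in frame *i*, the minimum distance to any
  same-class point of frame *i−1*, averaged. This is mathematically
  identical to the append-the-point-then-find-its-nearest-neighbour
  construction and approximates per-individual displacement while the
  colony is near-stationary (incubation/guard). A frame whose own or whose
  predecessor's class set is empty gets a missing value rather than 0 — an
  absent colony is "no information", not "no movement". The first frame is
  always missing.
* **Temperatures.** tempc = (tempf − 32)·5/9, computed at full precision
  and written with 6 significant digits (the archives' own rounding is
  unknown; 6 digits are more than any camera thermometer resolves).
* Eggs get counts only; no spatial metrics are defined for them.

**Moving averages** for the summary plots use a trailing window over the
most recent *n* non-missing observations, with partial windows at the
series start, so every frame of an animation has a defined value. The three
panels use windows 20 (counts), 2 (chick second-NN) and 20 (movement).

## Density-map counting (pengbot)

The counting network itself is out of scope; its output matrices are inputs.
A matrix is loaded from a MAT-file (auto-detecting a single 2-D numeric
variable, with a `var_name` override because the archived variable name is
not documented), delimited text, or NPY. Negative entries — numerical noise
— are clamped to zero with a logged count rather than rejected. The count is
the matrix total; rounding is **half away from zero**, since "round to the
nearest integer" is ambiguous at .5 and banker's rounding would surprise
anyone tallying animals. Kernel truncation at image borders is deliberately
**not** compensated: an individual straddling the edge contributes only its
in-frame mass (≈0.5 for a border-centred symmetric kernel), reproducing the
edge-effect undercount that real density counting exhibits. Rendering maps
density monotonically to brightness with a perceptually uniform colormap
(viridis), maximum density brightest.

## Method comparison

For a pair of per-image count series the signed difference is
first − second (positive ⇒ the second method under-estimates). Summaries
report the mean of the absolute differences, their **sample SD** (the
magnitude of disagreement is the quantity of interest, and the published
description removes signs before averaging; a `signed_sd` flag computes the
signed-difference SD as a sensitivity check, since the archived spreadsheet
is the only place the convention could be verified), the proportion of
images with |diff| ≤ 1, and the over/under/equal tallies. Rows missing
either count are dropped with a log message. Swapping the pair order negates
every difference, swapping the over/under tallies and preserving the
magnitude statistics — property-tested.

## The synthetic colony

The generator's defaults describe a mid-sized Pygoscelis colony and the
documented crowd behaviour; they are fixed study conditions, not tuning
knobs:

* **Nests**: 12 sites, hard-core (rejection-sampled) placement with ≥60 px
  separation in a 1000×750 px frame, 40 px from the border. Hard-core
  spacing matches visibly spaced real nests and keeps neighbour metrics
  stable.
* **Phenology**: adults present on the nest with probability 0.95 per
  frame; two eggs per nest, visible only when the incubating adult is off
  the nest (on a real nest the eggs are underneath the adult and cannot be
  clicked); chicks replace eggs at frame 40 of 100, standing 16–18 px from
  the parent during the guard phase; from frame 70 (crèche onset) chicks
  abandon nests for 3 shared huddle sites (σ = 12 px within a huddle) placed
  clear of nests, which collapses the chick second-nearest-neighbour
  distance — the phenology signal the metric exists to detect.
* **Motion**: per-frame Gaussian position jitter, σ = 2 px (6 px for
  crèched chicks).
* **Volunteers**: 10 per image; detection probabilities adult 0.95, chick
  0.70, egg 0.40 (chicks and especially eggs are often missed); isotropic
  Gaussian click noise σ = 3 px; Poisson false positives (mean 0.2 per
  volunteer per image) labelled adult/chick/other 0.5/0.3/0.2; each
  volunteer's marks truncated at 30 per image in encounter order. The
  per-class detection rates are plausible values chosen once — no published
  estimates exist.
* **Density matrices**: one discrete Gaussian kernel per adult or chick,
  normalised to unit mass on its full footprint *before* edge truncation;
  kernel σ interpolates linearly from 2 px at the image top to 6 px at the
  bottom, so distant individuals are small and bright, as camera perspective
  dictates. Eggs contribute nothing.

All randomness flows from the scenario seed; writing a dataset also writes
a JSON sidecar with every generating parameter.

**What passing tests show — and don't.** On this simulated colony the full
pipeline recovers per-frame adult counts to within ±1 on ≥95 % of 100 frames
and density sums count interior individuals exactly. The simulator omits
occlusion, snow obscuration, camera shake, illumination change and
volunteer-skill heterogeneity, all of which degrade real annotations; the
tests therefore validate the *processing* — clustering, filtering, metric
algebra, format round-trips — not the field accuracy of citizen-science or
density counting, which can only be judged against expert gold-standard
annotation of real images.

## Numerical and degenerate-input conventions

* Missing values are `NA` in files and NaN/`pd.NA` in memory; a consensus
  row with all annotation fields missing encodes "no penguins identified".
* Empty click sets cluster to empty output (not an error); empty point sets
  yield missing metrics; an empty metric table cannot be plotted or
  summarised (error).
* Oracle tolerances in tests are 1e-9 for metric/brute-force agreement and
  1e-6 for unit-kernel mass (limited by truncating the Gaussian at 4σ).
* Problem sizes in the test-suite and the acceptance script — 100-frame
  scenarios, 1000 random point sets of ≤200 points, 50 density kernels —
  are the package's chosen desk-scale study conditions: large enough to
  exercise every code path and estimate rates with useful precision, small
  enough that the whole suite runs in a couple of minutes on one CPU.

## Known limitations

* The consensus clustering is a documented re-design; cluster assignments
  will not match the original archived aggregation click-for-click.
* `num_markings` dedup means the "no click lost" conservation property holds
  exactly only when each volunteer clicks each individual at most once.
* Movement is meaningful only while displacement per frame is below half
  the inter-individual spacing; past crèche onset it reads as a
  change-point signal, not a displacement estimate.
* Density counting cannot separate adults from chicks, and inherits the
  edge-effect undercount by design.
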