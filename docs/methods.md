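# Methods

## Scope and model

`colonynet` implements a colony-topology assay for 2D fluorescence images of
stained nuclei. The measured object is the *cell graph*: nodes are nucleus
centroids, edges are assigned by a deterministic Waxman rule, and the
quantities of interest are the mean degree k, the global clustering
coefficient cc, the characteristic path length cpl, and the small-world
coefficient SW relative to a size-matched Erdős–Rényi (E–R) null. Dose
groups are compared per metric with an unpaired two-tailed Student's t-test.

The assumptions baked into the pipeline:

* nuclei are bright, roughly elliptical objects on a darker background, so
  Otsu thresholding of a noise-shrunk image separates them;
* touching nuclei are separable by the distance-transform watershed, i.e.
  their fused silhouette is waist-shaped;
* the spatial arrangement of nucleus *centers* carries the biologically
  relevant signal; intensity is used only for detection;
* each image is an independent observation of its (cell line, dose) group —
  the image is the unit of replication in all t-tests.

## Segmentation chain

`denoise → binarize_otsu → morphological_cleanup → filter_small_and_border →
watershed_segment → extract_cells`, all deterministic.

* **Denoise.** Pixelwise Wiener-style shrinkage in a `filter_window_px`
  (default 3×3) window: the pixel is pulled toward the local mean by
  max(σ²−ν, 0)/σ², where σ² is the local variance and ν the image-wide mean
  of local variances — the classical estimator for constant-power additive
  noise. A constant image passes through unchanged, and the output never
  leaves the input's intensity range.
* **Threshold.** Otsu's maximum between-class-variance threshold; pixels
  strictly above threshold are foreground. A constant image raises an
  explicit degenerate-histogram error.
* **Morphology.** Opening then closing with a 3×3 square (Chebyshev disc of
  radius 1). The square element is chosen over the 4-connected diamond so
  that large convex shapes are exactly invariant; the radius is
  configurable (`opening_radius`).
* **Size/border filter.** Connected components (8-connectivity by default,
  configurable to 4) with *strictly fewer* than `min_component_px` = 8 pixels
  are removed — a planted 7-px component disappears, an 8-px one survives —
  and components touching any image edge are suppressed when `clear_border`
  is set (default), before watershed.
* **Watershed.** Relief = −EDT(mask). Minima shallower than `hmin_depth`
  (default 2 distance levels) are filled by grayscale erosion-reconstruction
  (h-minima imposition) before flooding, suppressing the spurious one-level
  basins that otherwise over-segment; flooding is masked to the foreground so
  every foreground pixel gets exactly one label. The default depth of 2 is
  the smallest value that removes 1-level noise basins while preserving the
  ridge between two discs of radius 10 whose centers are 14 px apart
  (saddle depth ≈ 2.9).
* **Descriptors.** Geometric centroid; area as raw pixel count; perimeter as
  the chain-code estimate with diagonal weighting (regionprops convention);
  eccentricity from the region's second central moments including the 1/12
  per-pixel extent term (moment-ellipse convention; collinear regions are
  capped at 1−10⁻¹²); roundness 4πA/P². Coordinates are 0-based,
  pixel-centered, x = column, y = row, origin top-left.

Areas and perimeters are reported in pixels and not converted to µm; the
pixel size travels as metadata only.

## Cell graph

Link rule: α·exp(−d/(βL)) ≥ R, with defaults α = 1, β = 0.025 and
R ∈ {0.1, 0.05, 0.02}; R is the operative threshold and p = 1 − R is kept as
a reporting label only. This is equivalent to linking at distance
d ≤ d\* = βL·ln(α/R), with ties included. L is the largest pairwise
Euclidean distance among the image's nodes, recomputed per image by default
(brute force to n = 1000, convex-hull vertices beyond); a fixed L can be set
in the config to pin the length scale across images. Because d/L is
scale-free, rescaling all coordinates leaves the graph unchanged. Duplicate
coordinates link at distance 0; a single-node image yields an edgeless graph.
No stochastic (coin-flip) Waxman variant is provided — the rule used by the
assay is the deterministic threshold.

## Topology metrics and the E–R null

* cc: node average of C_i = 2E_i/(k_i(k_i−1)); nodes of degree < 2 contribute
  C_i = 0 and remain in the average. Computed on the dense adjacency via
  triangle counting (row sums of (A²∘A)/2); an independent pure-python
  enumeration serves as the test oracle.
* cpl: mean unweighted BFS shortest-path length over *reachable* unordered
  pairs, with the reachable fraction reported alongside. High-dose colony
  graphs fragment routinely, so dropping unreachable pairs (rather than
  failing or substituting ∞) is the working convention; an edgeless graph
  raises. Isolated nodes are kept (they affect cc through the degree-<2
  convention and the pair count through the reachable fraction).
* Null: G(n, m) with exactly the observed node and edge counts, m edges
  sampled uniformly without replacement; 20 replicates by default, seeded.
  SW = (cc/cc_rand)/(cpl/cpl_rand), the clustering-to-path-length ratio
  normalized by its random-graph expectation; SW > 1 ⇔ more clustered at
  similar path length than random. cc_rand = 0 (possible at very small m)
  raises rather than returning ∞.

## Synthetic colony generator

The generator stands in for the assay's micrographs, which are not publicly
deposited. It emulates: (a) the homogeneous vs. clustered layout contrast
between unirradiated and heavily irradiated colonies — a hard-core uniform
process (rejection-sampled, bounded attempts, explicit "field too crowded"
error) vs. a Thomas process (uniform parents, Gaussian offspring, out-of-field
displacements resampled); (b) per-image counts in the few-hundred range; (c)
elliptical nuclei with dose-increasing area, rendered as filled ellipses at
14-bit depth (stored in 16-bit TIFF) with additive Gaussian noise. Overlap in
the ground-truth label mask is resolved to the nearest center so truth stays a
partition, which watershed evaluation requires.

What it does **not** emulate: intensity texture and chromatin structure
inside nuclei, uneven illumination, focus drift, debris/artifacts, mitotic
figures, and any actual radiation biology — "dose" only indexes preset
parameters. Passing tests therefore demonstrate correctness of the
*computational* chain and the qualitative layout→topology link, not
performance on real micrographs.

Preset rationale. For a uniform layout in a square field the expected degree
at R = 0.05 is k ≈ n·π(d\*/A^{1/2})² ≈ 0.035·n independent of field size, so
presets put n ≈ 200–500 to sit at the k ≈ 7–9 degree scale typical of
unirradiated colonies. The five-dose series (0–8 Gy) moves counts from 500
down to 250, mean nucleus radius from 2.6 to 4.0 px, and clustering from none
through progressively tighter Thomas parameters (σ 110 → 18 px). The
matched-count pair preset (n = 250 both layouts, 1000×1000 px, 10 parents,
σ = 16 px) isolates the layout effect from the count effect; its clustering
strength was chosen to produce the above-vs-below-one style contrast in SW,
not to match any particular reported magnitude. All generators are pure
functions of (config, seed); dataset writing derives one child seed per
(dose, replicate) via `SeedSequence` spawn keys, making the ground-truth CSV
byte-identical across reruns.

## Statistics

Pooled-variance Student's t (df = n_a+n_b−2), two-tailed, implemented in
closed form with the p-value from the t distribution's survival function;
Welch's correction is available behind `welch = true`. Zero pooled variance
with equal means returns p = 1 by convention; with unequal means it raises.
P-values are raw — no multiple-testing correction — and the run log states
this. Group summaries report mean ± sample sd; a single-observation group
reports sd = 0 with a warning rather than NaN.

## Numerical and degenerate-input choices

* Otsu on a constant image, cpl on an edgeless graph, t-test on n < 2,
  empty record lists, missing 0 Gy baseline: explicit errors, not NaN.
* Watershed on an empty mask: zero regions, no error.
* Segmentation labels are relabeled to consecutive 1..n after watershed.
* The uniform sampler's rejection budget is max(10 000, 500·n) candidate
  draws; geometrically infeasible requests surface as the same bounded-budget
  error.
* Eccentricity of sub-3-pixel fragments (possible only as watershed
  artifacts) is reported as 0.

## Problem sizes in tests

The test-suite and acceptance checks run at deliberately moderate scale —
700–1000 px fields, 200–250 nuclei, 10 seeds per condition, 10–20 E–R
replicates — sizes at which every statistical assertion (sign tests at
p < 0.01, t-tests at p < 0.05, null calibration within ±0.2) is already
stable under the fixed seeds used.

## Known limitations

* Rasterization inflates eccentricity for small nuclei: ideal circles of
  radius ~6 px measure e ≈ 0.2 on average (≈ 0.14 at radius 10). Descriptor
  regressions therefore use radius ≥ 10 px circles.
* On heavily clustered layouts, overlapping nuclei merge and watershed
  under-splits, so detected counts can fall well below truth; the topology
  readout is computed on detected centers and remains discriminative, but
  per-dose detected counts are not an unbiased density estimate there.
* The SW of a *sparse* uniform geometric layout is itself well above 1
  (geometric graphs cluster far more than E–R at matched density), so only
  SW *contrasts* between conditions — not absolute SW magnitudes — are
  interpreted.
* cpl over reachable pairs makes fragmented graphs look "short"; always read
  cpl together with the reported reachable fraction.
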