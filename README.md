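# colonynet

Quantifying how ionizing radiation reorganizes cancer-cell colonies, through
the topology of the network their nuclei form.

Colonies grown in a clonogenic assay and imaged by fluorescence microscopy
(DAPI/Hoechst-stained nuclei) look homogeneous when unirradiated and become
irregular and locally clumped at high dose. `colonynet` turns that visual
impression into numbers: it segments nuclei from 2D micrographs, connects
their centers into a spatial graph, and measures how "small-world" the
resulting network is relative to a size-matched random graph. The
small-world coefficient rises sharply when cells cluster, making it a
candidate readout for cell radiosensitivity. The package is aimed at
radiation biologists and image analysts who want that readout as a tested,
reproducible pipeline — plus a synthetic colony generator for validating
every stage against known ground truth.

## The method

1. **Segmentation** — grayscale image → adaptive (Wiener-style) noise
   shrinkage → Otsu binarization → morphological opening/closing → removal of
   components under 8 px and of border-touching structures → watershed on the
   negated Euclidean distance transform with h-minima imposition. Each
   nucleus yields a centroid plus shape descriptors (area *A*, perimeter *P*,
   eccentricity *e* = √(1 − b²/a²), roundness 4π*A*/*P*²).
2. **Cell graph** — nuclei centers become nodes; a pair (u, v) at Euclidean
   distance *d* is linked by the Waxman rule

   *p*(u, v) = α·e^(−d/(βL)) , link ⇔ *p*(u, v) ≥ R,

   with α = 1, β = 0.025, L the largest pairwise distance in the image and
   cut-off R ∈ {0.1, 0.05, 0.02} (reported as p = 1 − R). The rule is a
   deterministic distance-threshold graph of radius d\* = βL·ln(α/R).
3. **Topology** — mean degree k; clustering coefficient cc (node average of
   C_i = 2E_i/(k_i(k_i−1))); characteristic path length cpl (mean BFS
   shortest path over reachable pairs). Small-world-ness against Erdős–Rényi
   G(n, m) graphs with the same node and edge count:

   SW = (cc/cc_rand) / (cpl/cpl_rand).

4. **Statistics** — per-image metrics of each dose group are compared with
   the 0 Gy group by a two-tailed unpaired Student's t-test (pooled
   variance), α = 0.05, raw p-values.

Since no public image set accompanies the assay, the `synthetic` module
generates ground-truthed colonies: a hard-core uniform point process for
unirradiated layouts, a Thomas cluster process for irradiated ones, elliptical
nuclei rendered at 14-bit depth with additive Gaussian noise.

## Worked example

```sh
colonynet run --config demo.cfg --out demo_out
```

with `demo.cfg` containing

```ini
preset = minimal        # 2 doses x 700x700 px x 200 nuclei
images_per_dose = 5
seed = 1
```

prints

```
pipeline complete: 10 images -> demo_out
line metric  dose  p_value  significant
 SYN     sw   8.0 0.006339         True
 SYN   area   8.0 0.000001         True
```

and `demo_out/summary.csv` holds the per-dose means ± sd:

```
dose metric   mean    sd
 0.0 k_mean  5.303 0.345
 0.0     cc  0.560 0.016
 0.0    cpl 10.065 2.313
 0.0     sw  7.222 1.002
 8.0 k_mean  6.726 1.529
 8.0     cc  0.901 0.027
 8.0    cpl  1.199 0.130
 8.0     sw 15.730 5.091
```

Reading: the uniform "0 Gy" colonies form one well-connected network (long
paths, moderate clustering), while the clustered "8 Gy" colonies fragment
into dense cliques — clustering rises toward 1, paths collapse toward 1 hop,
and the small-world coefficient roughly doubles. The t-test on per-image SW
rejects equality of the groups (p ≈ 0.006 < 0.05), and nuclear area rises
with dose as configured in the preset. Per-image records are in
`metrics.csv` / `cells.csv` / `edges.csv`; `run_log.txt` captures every
parameter and seed.

The library surface mirrors the CLI: `simulate_colony`, `segment_image`,
`build_graph`, `small_worldness`, `compare_doses`, `run_pipeline`.

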