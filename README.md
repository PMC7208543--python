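# mumri — motor unit territory mapping from dynamic diffusion-weighted MRI

Single human motor units contracting during graded electrical nerve
stimulation show up in diffusion-weighted dynamic MRI as localized signal
voids. Near its activation threshold a motor unit fires probabilistically in
an all-or-none fashion (*alternation*), so across a fine current staircase a
spatially consistent region flickers between baseline and void intensity.
`mumri` turns that flicker into quantitative motor unit anatomy: binary
territory maps, cross-sectional area (CSA), maximum/minimum Feret diameters,
a five-class shape taxonomy (elliptical, crescent, circular, spider, split),
activation thresholds and alternation current ranges — together with a
phantom simulator that makes every stage testable against known ground
truth, and the observer-agreement statistics (ICC, Bland–Altman) used to
establish that such a pipeline is reproducible.

It is written for researchers in neuromuscular imaging and
electrophysiology who want to analyse stimulated dynamic scans, prototype
protocols in simulation, or validate their own analysis against a phantom
with recoverable answers.

## The method

A session has two scans over a 2D muscle slice (one image per second):

1. **Coarse-grain scan** — the stimulation current ramps up in 0.1–0.5 mA
   steps. The mean intensity of a region of interest is plotted against
   current; the *inflection point* of a two-segment piecewise-linear fit is
   the current at which muscle activity first appears, and the fine scan
   starts five steps above it (I_max).
2. **Fine-grain scan** — the current descends from I_max in 0.01 mA steps,
   each level held for 5 repeats (the standard protocol is 216 levels =
   1080 dynamics). Units near threshold alternate.

Extraction then proceeds per unit:

- voxels whose intensity trace is bimodal (optimal two-cluster split with a
  separation ≥ 4 pooled within-cluster SDs; pure noise separates by ~2.7)
  are candidates;
- candidates are clustered by *co-firing*: binary firing vectors with
  pairwise r² ≥ 0.6 (and positive r) join; each connected group is one
  putative unit — this is also what binds the disjoint parts of a split
  unit together;
- frames inside the unit's alternation window are grouped into
  fired/not-fired by a two-means split of the seed-region trace, the two
  group means are subtracted (`mean(no void) − mean(void)`), the map is
  normalised to its maximum, and voxels ≥ 0.5 of the maximum form the
  territory;
- morphometry on the territory's voxel-square outline: CSA = voxel count ×
  voxel area; Feret diameters by rotating calipers on the convex hull;
  shape class from component count, solidity and aspect ratio; for split
  units the border-to-border component gap;
- per unit, the activation threshold (lowest current with any firing) and
  the alternation range (current span of levels with mixed outcomes).

The firing model used by the simulator is logistic:
`P(fire | I) = 1 / (1 + exp(−(I − threshold)/width))`, exactly 0.5 at
threshold, with Rician noise on the magnitude images and an optional
mechanical-coupling dilation of the void region.

## Worked example

The five-minute smoke test plants three units of different shape and
threshold in three muscles, simulates the fine staircase, and runs the whole
chain:

```sh
mumri demo --seed 0 --out-dir demo_run
```

prints

```
detected 3 unit(s); seed 0; config dbb7e982377f
 planted     shape  thr mA  found class ok  dCSA mm2  dFmax mm  dFmin mm
       0   ellipse   10.00   True     True      0.00      0.00      0.00
       1  crescent   10.30   True     True      0.00      0.00      0.00
       2     split   10.60   True     True      0.00      0.00      0.00
```

— all three planted units are detected, each classified with its planted
shape, with zero error in CSA and both Feret diameters, and in the planted
recruitment order. `demo_run/` holds the simulated series (NIfTI), schedule
(CSV), per-unit firing vectors and metrics (JSON/CSV) and QC difference-map
images; every output embeds the seed and config hash, and reruns are
byte-identical.

The `examples/` directory has one short narrative script per capability
(simulation, coarse profile, extraction, morphometry, agreement
statistics); each prints the numbers it computes and what they mean. The
same operations are available as library functions (`simulate_series`,
`roi_profile` / `detect_inflection`, `extract_units`, `measure_unit`,
`agreement`, …) and as CLI subcommands (`simulate`, `coarse`, `extract`,
`metrics`, `stats`, `demo`).

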