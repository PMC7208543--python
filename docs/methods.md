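# Methods

This note documents the models, algorithms, parameters and design choices
behind `mumri`, and what its simulation studies do and do not establish.

## Signal model and phantom

A dynamic scan is a 2D slice imaged once per TR (default 1 s) while the
nerve is stimulated once per dynamic. The phantom represents a muscle slice
as an integer label mask with a uniform baseline intensity per muscle
(default 100, arbitrary units). Each planted motor unit is a binary
territory with four behavioural parameters:

| parameter | meaning | default |
|---|---|---|
| `threshold_mA` | logistic midpoint: 50% firing probability | 10.0 |
| `firing_width_mA` | logistic scale; the 10→90% span is ≈ 4.4 × width | 0.05 |
| `void_fraction` | multiplicative signal drop when the unit fires | 0.4 |
| `coupling_dilation_vox` | mechanical-coupling halo (binary dilation, 8-connected) | 0 |

Firing is all-or-none and spatially uniform over the territory: per
dynamic, the unit fires with probability
`P(fire | I) = 1/(1 + exp(−(I − threshold)/width))`, exactly 0.5 at
threshold; width 0 degenerates to a step (0.5 at threshold by convention).
The published account of the phenomenon is probabilistic all-or-none firing
around a threshold without a functional form; the logistic is this
package's parameterisation, chosen because its single scale parameter maps
monotonically onto the observed alternation current range. Real recruitment
data does not constrain the tail shape, so nothing here should be read as a
claim that recruitment noise is exactly logistic.

Fired units multiply the signal by `void_fraction` over the territory
dilated by the coupling halo; the in-vivo reports do not quantify void
depth, so 0.4 is a free simulator parameter (deep enough to be obvious,
shallow enough that the Rician floor matters). Noise is Rician — Gaussian
noise of scale `noise_sigma × baseline` added to the real and imaginary
channels before the magnitude — with `noise_sigma` defaulting to 0.03, a
typical SNR ≈ 33 magnitude image. Geometry defaults to the acquisition
used in practice: 1.5 × 1.5 mm in-plane voxels, 7.5 mm slice.

What the phantom does **not** emulate: diffusion/IVIM signal physics, EPI
distortion, subject motion, partial-volume gradations at territory edges
(voids are binary before noise), through-plane effects and cross-talk
between slices. Passing recovery tests therefore demonstrates the analysis
chain is correct and well-conditioned at realistic SNR, not that in-vivo
data will be as clean; in particular real territory borders are gradual,
and the mechanical-coupling halo means in-vivo maps may over-estimate true
fibre territories (simulate `coupling_dilation_vox=1` to study that bias).

Schedules follow the two standard protocols. Coarse: ascending ramp, one
dynamic per level, step 0.1–0.5 mA (values outside that band warn but run).
Fine: descending staircase from I_max, 0.01 mA steps, 5 repeats per level;
the full protocol is 216 levels = 1080 dynamics; the planner rejects
staircases that reach non-positive current. I_max is the inflection current
plus five coarse steps.

## Coarse-ramp inflection

The ROI profile is the mean intensity over a muscle label per current
level. The inflection is found by exhaustive two-segment continuous
piecewise-linear least squares: every interior measured current is tried as
the hinge knot `y ~ 1 + x + (x − knot)₊`, the knot minimising the RSS wins,
and the result is reported at that measured level. The published analyses
name the inflection concept but not an algorithm; the fitted method is this
package's choice.

Significance: the hinge must (a) slope down relative to the first segment
and (b) improve on a single straight line by an F-type change statistic
`(RSS_line − RSS_hinge)/(RSS_hinge/(n−3)) ≥ 30`. Because the knot is
selected by search, the null distribution is inflated relative to a
textbook F(1, n−3); simulated nulls (flat noise, pure linear decline,
n = 40) put the 99.9th percentile near 20, while genuine recruitment breaks
score in the thousands, so 30 separates the regimes with wide margins on
both sides. An earlier criterion based on comparing the per-step slope
change to the first segment's residual SD was abandoned: the pre-onset
logistic droop inflates that SD and produced false "no inflection" signals
on otherwise clean profiles. The statistic is invariant to affine intensity
rescaling.

Estimator bias worth knowing: the breakpoint model assumes the
post-onset decline is locally linear. When recruitment is sparse (few
units, thresholds ≳ 4 ramp steps apart) the profile is a coarse staircase
and back-extrapolation lands early by up to the inter-threshold spacing;
when the ramp continues past full recruitment, the flat tail drags the knot
around. The inflection-recovery study therefore uses the conditions the
protocol is designed for — a pool of 18 small units at 0.1 mA threshold
spacing, ramp ending while recruitment is still in progress (the scan stops
once contrast is clear) — and recovers the lowest planted threshold within
±1 level in ≈99% of runs at 2% noise.

## Unit extraction

**Candidate voxels.** Each masked voxel's trace is split into two clusters
by exhaustive 1D two-means (optimal for 1D); a voxel qualifies if the
cluster-mean gap is ≥ `min_separation` (default 4) pooled within-cluster
SDs and the low (void) state recurs on ≥ `min_events` (default 3)
dynamics. The default operating point comes from the statistic's behaviour,
not tuning: a forced two-means split of pure Gaussian noise concentrates
near 2.7 within-SDs (max ≈ 3.3 over thousands of voxels at realistic series
lengths), while a genuine void at default contrast separates by
`(1 − void_fraction)/noise_sigma = 20`.

**Co-firing clustering.** Candidate voxels are binarised at their own
two-means midpoint and linked when their binary firing vectors correlate
positively with r² ≥ `cofire_r2` (default 0.6, between the reported
same-unit ≈ 0.87 and different-unit ≈ 0.45 values); connected groups are
putative units, groups smaller than `min_unit_voxels` (default 3) are
dropped. The positivity gate matters: two voxels firing on exactly
complementary frames have r² = 1 and must not be merged. Units with
identical thresholds and widths can in principle merge — resolving truly
overlapping or synchronised units is out of scope, matching the practice of
excluding overlapping regions from analysis.

**Alternation window.** The frames used for a unit's difference map are
restricted to its own alternation zone (span of mixed-outcome levels,
padded by `window_pad_levels` = 5 levels each side; for a deterministic
unit, the bracketing transition levels). This is essential with several
units in one staircase: grouped over all dynamics, the fired/not-fired
split of one unit correlates with the recruitment of every unit above it,
and their territories leak into its map (observed as merged
pseudo-"split" maps before the window was introduced). Whether the
original manual analyses used all dynamics or only the alternation period
is not stated; the windowed choice is recorded here as this package's.

**Frame grouping and maps.** The seed-region mean trace is two-means
partitioned (lower cluster = fired); indistinguishable clusters raise a
"no alternation" signal rather than returning garbage. The difference map
is `mean(not-fired) − mean(fired)` per voxel inside the mask; it is linear
in the series. Negative values are clipped to zero (the sources are silent
on negatives), the map is normalised to its maximum, and the territory is
`normalised ≥ 0.5` with sub-`min_unit_voxels` components removed
(8-connectivity). The 0.5 fraction is the published operating point;
`threshold_sweep` reports CSA/Feret across fractions for threshold QC, and
territories shrink monotonically (set inclusion) as the fraction rises.

**Alternation statistics.** Per level (ignoring excluded dynamics): the
activation threshold is the lowest current with ≥ 1 fired repeat; levels
with 1–4 of 5 repeats fired are the alternation zone; the alternation range
is `max(mixed) − min(mixed)` currents, 0 with no mixed level. An
alternative convention, `(lowest all-fired) − (highest none-fired) − step`,
differs by exactly one step for a contiguous zone; the direct-count
convention is used throughout. A unit that fires at every level gets a
right-censored flag (the staircase never reached its quiet zone). Note the
threshold statistic sits ≈ 2 × width below the logistic midpoint (the
lowest current where any of 5 repeats fires): it is a "first activity"
measure, not a midpoint estimate, and the recovery study accordingly scores
it against the same statistic on the ground-truth firing draws.

## Morphometry

Geometry is computed on the union of voxel squares (corner polygons), not
voxel centres, so a single voxel has physical extent: Feret min 1.5 mm,
Feret max 1.5·√2 mm at default voxels. CSA is voxel count × voxel area.
Feret diameters are caliper widths of the convex hull: the maximum is the
hull diameter, the minimum the smallest width over hull edges (the minimum
width of a convex polygon is attained perpendicular to an edge). For
multi-component territories the hull spans all components jointly — one
caliper pair restricts "the object". The implementation is cross-checked
against an independent projection-sweep oracle (0.1° grid with local
refinement; the kinked minima of a polygon's width function make an
unrefined grid converge only linearly) to 1e-6 mm.

Component analysis uses 8-connectivity. The split-component gap is the
minimum distance between the component boundary polygons (shapely); planted
gaps are realised as whole empty voxel columns, so a requested 4.3 mm gap
on a 1.5 mm grid is planted and recovered as 4.5 mm — within half a voxel.

Shape classification is a rule cascade: **split** if ≥ 2 components of at
least `min_unit_voxels` each; else with solidity s = area/hull area and
aspect a = FeretMax/FeretMin: **spider** if s < 0.6, **crescent** if
s < 0.85, **circular** if a < 1.3, **ellipse** otherwise. The in-vivo
taxonomy was assigned by eye; these numeric cutoffs are this package's
operational definitions (configurable), chosen so that clean geometric
exemplars of each class sit well inside their band, and they are documented
as such rather than attributed to the original observers. The canonical
fixture set (3 exemplars per class, generated by `make_territory`)
classifies 15/15 noise-free and ≥ 90% after recovery through the full
difference-map route at 3% noise.

One rasterisation caveat: centre-inside rasterisation has boundary area
error of order voxel × perimeter, so pixelated CSA of an analytic shape
converges to the analytic area only as the grid refines; at 1.5 mm voxels a
10 × 4 mm ellipse can be off by a few mm². Recovery tests therefore compare
recovered maps against *planted pixelated* territories, which is also what
an observer of the images could at best recover.

## Statistics

Shapiro–Wilk, one-way ANOVA (between muscles), unpaired two-tailed
Student's t (between age bands, default cut 40 years, configurable) and
Pearson correlation delegate to scipy.stats; type-I error of the group
comparisons is simulation-calibrated in the tests. The intraclass
correlation is computed from the two-way ANOVA mean squares as the
absolute-agreement form, single measures by default
(`(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)`), with an
`measures="average"` switch; the published analyses name the two-way mixed
absolute-agreement family without specifying single vs average, and single
is the conservative default. Bland–Altman bias is the mean paired
difference and the coefficient of repeatability 1.96 × SD of the paired
differences (no formula was published; this is the conventional
definition). The implementation is cross-checked against pingouin's
ICC(A,1)/ICC(A,k) and against R's `shapiro.test`/`cor.test` on frozen
vectors.

## Validation studies and their problem sizes

Each study in `mumri.validation` fixes its conditions once; the acceptance
script reseeds them from `--seed`:

- **Feret oracle**: 200 random 12×12 masks; caliper vs refined projection
  sweep agree to < 1e-9 mm (band 1e-6).
- **Morphometric recovery**: 50 phantoms, one random ellipse each
  (axes 8–16 × 4–7 mm, random orientation), 48×48 grid, 3% noise, 150-dynamic
  staircase through threshold; recovered CSA within 3 voxel areas and both
  Feret diameters within 1 voxel of planted in 100% of runs (the in-vivo
  scan–rescan repeatability is of the same order: ~3 voxels CSA, ~1 voxel
  Feret).
- **Alternation**: 100 single-unit staircases, widths 0.002–0.05 mA;
  measured range vs width Pearson r ≈ 0.9; threshold statistic matches the
  ground-truth firing statistic exactly (≤ 0.02 mA band).
- **Co-firing**: 50 two-unit phantoms (thresholds 0.3 mA apart);
  within-unit r² ≈ 0.98 vs cross-unit ≈ 0.15; same-unit wins in 100% of
  runs — the qualitative pattern reported in vivo (0.87 vs 0.45).
- **False positives**: 50 pure-noise staircases; zero units detected in
  100% of runs.
- **Inflection**: 100 coarse ramps as described above; ≈ 99% within ±1
  level.
- **Demo**: the 3-unit end-to-end run, deterministic per seed.

Sizes were chosen so each study gives stable rates while the whole battery
runs in seconds on one core; all phantom grids are smaller than a real
160 mm field of view but large relative to the planted units, which is the
ratio that matters for the detectors.

## Known limitations

- Territory edges are binary in the phantom; partial-volume behaviour of
  the 0.5 threshold on real, graded voids is untested here (the published
  threshold sweep addresses it on in-vivo data).
- Units with indistinguishable firing vectors merge; overlapping-unit
  delineation is out of scope.
- The activation-threshold statistic is biased below the logistic midpoint
  by ≈ 2 × width by construction; compare like with like.
- The inflection fit assumes the ramp ends before recruitment saturates;
  profiles with a long post-saturation plateau should be truncated first.
- Single-slice 2D analysis only; no claim about territory continuity along
  the muscle.
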