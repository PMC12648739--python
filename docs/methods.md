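# Methods

This note documents the models, rules and numerical choices behind
`germtrack`, what the synthetic-data generator does and does not emulate,
and the problem sizes used in the test-suite and acceptance script.

## Inputs and conventions

The pipeline consumes a time-ordered RGB series (default interval 1 h), a
mm-per-pixel scale (default 0.05 mm/px, ≈5,000 px per wheat seed), per-frame
segmentation label maps with classes background / seed body / root /
seedling, and per-seed ROIs. Coordinates are (row, col), origin top-left,
0-based; boxes half-open. Frame order is the lexicographic filename sort,
overridable by a `manifest.csv`. Label maps are single-channel 8-bit PNGs —
chosen over RGB palettes so round-trips are lossless by construction.

Optional registration to frame 0 estimates translation by phase correlation
on the grayscale mean (rotation, when requested, by exhaustive search over
±2° in 0.1° steps), applies whole-pixel shifts (nearest-neighbour for label
maps), and flags frames whose estimated shift exceeds 10% of the frame size
rather than applying an implausible correction. Alignment is applied
per-frame; residual shifts are reported in the series object.

## Root-tip tracking

Each root is a temporal directed graph: empty before its emergence frame
t_e, holding only the skeleton point at the seed coat at t_e − 1, and
growing by one accepted tip per frame afterwards. Acceptance of a candidate
tip P from the current tip V_t requires

* minimum route weight from V_t to P, where entering a skeleton pixel costs
  0 and any other pixel costs 1, moves 8-connected (uniform-cost search via
  `skimage.graph.MCP`; an independent Dijkstra oracle checks it in tests);
* a turn of at most 60°: cos(∠(V_{t−1}V_t, V_tP)) ≥ 0.5. The threshold is
  configurable (`cos_min`); 0.5 is the default. On the first extension the
  reference direction is origin → V_t; with a single vertex and no origin
  displacement no angle gate applies.

If no candidate qualifies, the graph is unchanged (zero growth that frame).
After `max_missed` = 5 consecutive frames with the root undetected the
track closes; a track also closes when its tip leaves the seed's ROI.
A graph *opens* on the first frame a skeleton component touches the seed
coat (origin within 6 px of the seed body) — whether or not its tip is
detectable yet — so emergence frames are recorded at first visibility. At
most three roots are tracked per seed (radicle + two laterals, ordered by
emergence, ties by clockwise angle from 12 o'clock around the seed
centroid).

Numerical-robustness rules layered on the core acceptance test, each a
package design choice:

* **Direction baseline.** Tip-to-tip direction vectors are measured over a
  baseline of ≥ 5 px of recent vertices. Hourly steps are often 1–2 px, and
  8-connected quantisation of such short vectors makes a 60° gate
  meaningless (a straight-growing root can appear to turn 63°).
* **Component gate and cost cap.** Candidates must lie on the same skeleton
  connected component as the track's current tip (components merge at
  crossings, so continuation is unaffected), and routes may bridge at most
  20 off-skeleton pixels. Both rules stop a paused track from hopping onto
  a neighbouring seed's root.
* **Step cap.** A tip may move at most 15 px per frame (≈0.75 mm/h at the
  default scale — generous for cereal radicles), scaled by the number of
  missed frames after dropouts. This prevents jumping to the far end of a
  merged stroke when two roots briefly overlap.
* **Tie-breaks.** At equal route cost the straighter continuation wins
  (the same 180°-preference that resolves crossings), then the nearer tip.

**Route length.** Cumulative root length sums the geometric length of
accepted routes. A route is measured as a polyline resampled every 4 px
(endpoints kept) rather than as raw 1/√2 chain steps: chain-code length
overestimates digitised curves by up to ~8% depending on orientation, and
corrected chain weights still carry ~4% orientation bias, while resampling
keeps the error well under 1% at root-scale curvature. Off-skeleton bridge
steps (the previous tip sitting a pixel off the freshly thinned skeleton)
are included — they are part of the same root centreline.

**Growth rates** are centred finite differences of moving-average-smoothed
lengths (window 5 frames, shrunk with a warning on short series). The frame
of fastest rate change is the peak |d rate/dt| with the first/last window
excluded, where edge padding inflates the second derivative.

## Skeletons and crossings

Masks are thinned with topology-preserving skeletonisation
(`skimage.morphology.skeletonize`); endpoints have exactly one 8-neighbour,
branch points three or more. Two branch points within 5 px (≈ the root
width at default resolution) are summarised by their midpoint (equivalent
branch point); clusters of three or more — the usual thinning residue of an
X-crossing between 3-px-wide roots — are treated as a single crossing
region centred on the cluster centroid. Root tips are skeleton endpoints
farther than 3 px from the seed body and seedling masks (a seed-boundary
roughness guard); each component's origin is its pixel nearest the seed
body.

Arm directions at a crossing are unit vectors from the centre to the point
15 px along each arm (or the arm's end): short-window vectors are stable
where tip-ward vectors wobble on curved arms. Four arms admit three
disjoint pairings scored by Σ|180° − angle|; the minimiser wins. Three arms
yield one best pair, the third arm unpaired. Scores are rounded to 10⁻⁶
degrees so exact geometric ties resolve by pairing order, not float noise;
when the two best pairings differ by < 5°, the pairing most consistent
with the tracked roots' recent growth directions is taken. Routes through a
resolved region must enter and leave via paired arms (traversal judged by
proximity to the centre, since thinning webs contain parallel paths).
Regions with five or more arms are not resolved; tracking falls back to its
angle/cost/step gates there.

## Traits and event times

* Area = pixel count × scale²; perimeter = length of the marching-squares
  boundary contour simplified by Douglas–Peucker (tolerance 1 px), which
  removes the staircase bias that makes rasterised circles measure ~10%
  long; roundness = 4πA/P²; length/width = sides of the minimum-area
  rotated rectangle of the boundary polygon (deterministic, unlike ellipse
  fits, and rotation-stable within ~3%).
* Coat colour = per-channel arithmetic means over the seed-body mask;
  change rates are 100·(v_t − v_0)/v_0.
* ExG = 2G − R − B on raw 8-bit channels (−510…510), no chromatic
  normalisation (exposed in config).
* Chloroplast biogenesis: threshold = mean ExG over all seedling pixels of
  the lot at the reference hour (80 by default; per-seed thresholds behind
  a flag); a seed greens at the first hour ≥ 5 of its seedling pixels
  exceed the threshold — the 5-px floor resists salt noise that a literal
  "any pixel" rule would trip on.
* Coleoptile emergence: first hour the seedling mask touches the seed body.
  Label maps carry disjoint classes, so contact is evaluated against the
  seed body dilated by 1 px; genuinely overlapping external masks are
  caught directly.
* Threshold times (2 mm germinated, 10 mm established) are first crossings
  on the frame grid — no sub-frame interpolation, so resolution equals the
  imaging interval.
* Lot phase time: first hour with ≥ ⌈0.75·n⌉ seeds in phase; the 15-seed
  standardisation samples without replacement with a recorded seed.
* Phase calls are trait-derived: IMB (no root), PRO (root < 2 mm), RE
  (≥ 2 mm, no seedling), SE (seedling mask non-empty). The 2 mm PRO/RE
  boundary is anchored to the "germinated" rule; seedling visibility, not
  greenness, defines SE (greening is timed separately).

## Vigor scoring

Speed groups come from two clusterings: Ward agglomerative clustering of
mean radicle-length curves (k = 3, labelled quick/medium/slow by ascending
mean time-to-2 mm), and affinity propagation (damping 0.5, preference =
median similarity, deterministic k-medoids fallback on non-convergence) on
per-genotype event-time summaries (median, IQR, censored fraction). More
than three AP clusters are merged by median-hour adjacency; fewer than
three map onto the ordered labels (1 → medium, 2 → quick/slow).

Uniformity of a phase's event hours is peak/span on the uncensored values:
peak = modal histogram-bin fraction (bin = imaging interval), span =
central-75% width (12.5th–87.5th percentile) in bins, floored at one bin;
the score min(1, peak/span) is 1 exactly when all events share one bin.
Censored seeds are counted and reported but excluded from the ratio —
whether they should directly penalise the score is left open deliberately.

The vigor matrix multiplies speed points (quick 3 / medium 2 / slow 1) by
the uniformity score per phase (PRO = protrusion, RE = 2 mm, SE =
chloroplast biogenesis, falling back to coleoptile hours when no greening
was observed) and sums the three phases (range 0–9; a missing phase
contributes 0 and is flagged). Overall high/medium/low classes cluster the
summed scores with affinity propagation **on a log scale**: the
peak-over-span construction is ratio-scaled (tight lots score ~10× loose
ones), so linear distances would collapse the lower tiers. Summing phases
before clustering (rather than clustering the per-phase score vectors) was
chosen for simplicity and monotonicity; the alternative is noted.

## The synthetic-data generator

`simulate_lot` emulates the phenomenology the pipeline is built for: a grid
of elliptical seeds (3 × 2 mm) that swell by a factor 1.3 in area over the
first 20 h of imbibition; per seed up to three roots emerging at Gaussian
times (radicle ≈ 40 ± 5 h by default; laterals follow the radicle, and
numbering is emergence-ordered) whose arc length follows a logistic law
(L_max 12 / 8 / 6 mm, rate 0.12 h⁻¹, inflection 18 h after emergence, 0.4 mm
visible at emergence) along downward polylines with per-step heading jitter
(5° sd, clipped to ±30° of the base heading); optional steering of adjacent
radicles through a common waypoint to produce exactly one crossing;
seedlings growing upward from the seed top at 0.3 mm/h that switch from
pale to green albedo at their greening hour. RGB frames add Gaussian pixel
noise (sd 3); label maps are rendered noise-free. Everything is
deterministic given the seed, and exact ground truth (per-frame lengths,
emergence frames, crossing events, event hours) is returned.

Deliberately **not** simulated: root hairs, moisture reflections and other
imaging artefacts, seed displacement during the experiment, occlusion by
condensation, and photorealistic texture. Passing recovery tests therefore
demonstrates correctness of the graph-tracking and trait logic on clean
masks, not robustness to segmentation failure on difficult real images —
on real data, mask quality bounds everything downstream.

Three presets drive the scenario tests: `no-crossings` (4 × 4 seeds, 96
frames), `one-crossing` (a seed pair with one steered crossing and a
lateral root forced to emerge after it), and `three-tier-vigor` (nine
genotypes, three per designed tier, 20 seeds each; tier spreads 1.5 / 3 /
10 h). The three-tier preset is a positive control: its tiers are designed
to be clearly separated so that failure indicates a scoring defect, not
sampling noise.

## Problem sizes

The test-suite tracks 20 simulated 16-seed lots of 96 frames for the
recovery checks, six crossing scenes, and the three-tier scenario twice;
`scripts/acceptance.py` uses eight recovery lots, five crossing scenes, one
RGB lot for greening recovery, and one three-tier scenario, which keeps a
single-CPU run in the tens of minutes. Recovery quality does not change
measurably between 8 and 20 lots (≈ 380 vs ≈ 950 tracked roots).

## Known limitations

* Tangles of ≥ 5 arms and repeated crossings of the same pair are not
  resolved; tracking relies on its local gates there, as accuracy in
  complex intersections is the method's known weak spot.
* Roots are not re-identified after total occlusion or track closure.
* The temporal graph assumes roots only elongate; retraction (e.g. seed
  movement) appears as zero growth, not negative.
* The uniformity score's absolute values depend on the bin width (the
  imaging interval); comparisons are meaningful within one protocol only.
* The classical colour-threshold segmentation is a deterministic fallback
  for clean, evenly lit scenes; it does not approach learned-model quality
  on real imagery.
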