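# Methods

`zfsentinel` implements a field protocol for using wild zebrafish
(*Danio rerio*) as biological sentinels: groups of six fish from each of
two sites are filmed from above in a 30.8 cm x 34 cm tank for 3 min,
and each fish is photographed for landmark morphometrics.  The package
turns tracking exports and landmark files into the protocol's social,
activity, and body-shape endpoints, runs the between-site statistics,
and ships a synthetic-data generator with known ground truth so every
stage is testable without the archived field data.

## Behavioral endpoints

All positions live on a common frame grid.  Missing detections are an
unavoidable feature of field tracking; gaps of at most `max_gap_frames`
(default 5) consecutive frames are filled by linear interpolation and
longer gaps are excluded from every metric (both numerator and
denominator of time averages).  The fraction of frames with an actual
detection — recorded before interpolation — feeds a quality gate: a tank
enters analysis only if every fish was detected in at least 80% of
frames (inclusive boundary; the threshold reads as a minimum).

Social measures, per fish, averaged over frames where the whole group
is tracked:

* **inter-individual distance (IID)** — mean Euclidean distance to all
  other group members, mm;
* **nearest-neighbour distance (NND)** — distance to the closest group
  member, mm (by construction NND <= IID frame by frame);
* **time in proximity** — seconds with *any* neighbour within two body
  lengths.  The threshold defaults to 1000 px, the standardization used
  when detection sizes are in the 400–500 px band; an mm-denominated
  threshold (`use_mm`, e.g. twice the mean standard length) is exposed
  for different optics.  The comparison is inclusive (<=), and the
  endpoint is also reported as a fraction of the valid tracked time.

Activity measures, per fish:

* **distance traveled** — summed step lengths between consecutive valid
  frames, mm;
* **swim speed** — distance over the valid tracked duration, mm/s (the
  identity speed x valid duration = distance holds exactly);
* **time in motion** — seconds whose backward-difference speed exceeds
  `motion_speed_threshold_mm_s`.  The protocol does not define "in
  motion"; the default is 5 mm/s (about half a body length per second
  for the smaller site's fish), configurable, with 0 making every
  moving frame count.  Backward differences with no smoothing keep the
  brute-force oracle trivial; smoothing is deliberately not applied.
* **tank exploration** — the arena is partitioned into square cells
  (default 10 mm; edge cells truncated at the walls); the visited area
  is the count of cells containing at least one valid position times
  the cell area, capped at the arena area, and is also reported as a
  percent of the arena.  The original metric's discretization is
  unknown, so absolute mm^2 values are not comparable across
  implementations — between-site contrasts are.

Fish values are collapsed to tank means before any between-site test:
the tank, not the fish, is the independent unit (12 tanks per site in
the reference design).

## Morphometrics

Seven landmarks per fish (mouth; posterior dorsal skull; anterior
dorsal fin; caudal fin; anterior anal fin; ventral surface; ventral
anterior skull), read from TPS files with `SCALE=` conversion to mm and
site/sex labels from a sidecar table (the TPS format has no such
fields).

* **standard length** — distance from mouth to caudal-fin landmark.
* **region areas** — absolute shoelace areas of the anterior (landmarks
  1-5-6-7) and posterior (2-3-4-5) quadrilaterals, computed on the
  original mm-scale landmarks because size itself is informative; the
  posterior/anterior ratio is the size-free shape summary.
  Self-intersecting polygons warn with signed-area diagnostics.
* **generalized Procrustes analysis** — each configuration is centered,
  scaled to unit centroid size, and iteratively rotated to the running
  consensus until the consensus moves by less than `tol` (1e-10) or
  `max_iter` (100) rounds.  Rotations come from the closed-form 2-D
  orthogonal fit (reflections disallowed — all photographs share one
  orientation).  The output orientation is standardized by rotating the
  consensus onto its principal axes (sign fixed deterministically), so
  aligned coordinates are invariant to how the input photographs
  happened to be oriented.  An orthogonal tangent-space projection at
  the consensus is on by default; at within-species shape variation its
  effect is below 1e-4 and the suite asserts projected and unprojected
  coordinates agree to that level.
* **shape PCA** — principal components of the aligned coordinates
  flattened to 14-vectors (relative warps with uniform weighting,
  alpha = 0 — the variance decomposition tpsRelw reports in default
  use).  Thin-plate-spline bending-energy weighting and deformation
  grids are out of scope.  Component signs are fixed by making each
  loading's largest-magnitude entry positive; numerically null axes
  (the four similarity dimensions) are dropped, so the retained
  variance fractions sum to 1.

One alignment caveat worth knowing: a displacement planted at a single
peripheral landmark (e.g. the caudal fin) is partially absorbed by the
removed similarity transforms and redistributed across landmarks (the
"Pinocchio effect").  Group differences therefore concentrate cleanly
only at landmarks near the centroid; the tests assert concentration
where alignment theory predicts it.

## Statistics

* Behavioral endpoints: Welch two-sample t on tank means (site1 vs
  site2).  `welch_t_from_summary` recomputes t from printed
  mean +/- SEM tables, reporting the pooled df alongside the
  Welch–Satterthwaite df.
* Shape: two-factor crossed MANOVA (Population, Sex, interaction) with
  Pillai's trace per term, built from Type II scatter matrices (each
  main effect against the model containing the other; the interaction
  against the additive model; error scatter from the full model) with
  the standard F approximation.  Responses are PC scores retaining >=
  99% of shape variance (configurable) — the original response set is
  ambiguous, and retaining essentially all variance makes the choice
  immaterial.  Type II is also used for the area-ratio two-way ANOVA
  because the field sample's sex ratios are heavily unbalanced (62/9
  and 49/23); the choice is logged in every report.
* Area ratio: two-way ANOVA with interaction + Tukey HSD over the four
  Population x Sex cells (Tukey–Kramer for unequal cell sizes).
* Posterior vs anterior area: Wilcoxon signed-rank on paired
  differences, zeros dropped, average ranks for ties.  The exact null
  distribution is computed by dynamic programming over the doubled
  ranks for n <= 25 non-zero pairs (this stays exact under ties, which
  off-the-shelf exact routines refuse); larger n uses the normal
  approximation with continuity and tie corrections.
* Standard length: Kruskal–Wallis with tie correction across the four
  site x sex groups.

Reported df strings in the source tables that are internally
inconsistent (e.g. an H statistic exceeding its printed df at a
non-matching p) are treated as typographic artifacts; correct df are
computed and reported.  No multiple-testing correction is applied
across endpoint families, mirroring the protocol.

## Synthetic data generator

**Trajectories.** Each fish is a correlated random walk: its heading is
the angle of `persistence * u(heading) + cohesion_weight * (centroid -
position) / cohesion_length_mm` plus von Mises noise; per-frame speeds
are gamma draws (mean `mean_speed_mm_s`, shape `speed_shape`); walls
reflect (tanks have walls, so no periodic wrap-around); initial
positions are uniform over the arena.  The centroid attraction is
deliberately *distance-proportional* (a spring reaching full weight at
`cohesion_length_mm`) rather than a unit bearing vector: constant-
magnitude attraction collapses a six-fish group to a ~10 mm ball at any
workable weight, which saturates the proximity endpoint at both sites
and destroys the inter-individual distance scale, whereas the spring
form lets groups equilibrate at realistic spreads.  Every random draw
comes from a per-fish substream (`SeedSequence(seed, spawn_key=(site,
tank, fish))`), so output is bit-reproducible and adding a fish never
perturbs existing trajectories when cohesion is zero.

The **paper-like preset** encodes the reference study's conditions: 2
sites x 12 tanks x 6 fish x 180 s at 30 fps; Site 1 faster (14 vs
9 mm/s) and barely cohesive (weight 0.2 at 1000 mm spring length vs 0.8
at 300 mm); calibration 10 px/mm so the 1000 px proximity threshold is
100 mm in a 308 x 340 mm arena.  Two contrasts are deliberately *not*
planted, matching the study's null findings: the gamma speed shapes are
solved per site so both spend the same expected fraction (~11%) of time
below the 5 mm/s motion threshold, and Site 1's noisier headings
(kappa 2.15 vs 8) make its faster fish retrace their paths enough that
per-fish area coverage matches Site 2's.  With these settings the
generator reproduces the study's full qualitative pattern: Site 2 more
cohesive (higher proximity time, lower IID), Site 1 faster and
longer-ranging, no difference in time-in-motion or exploration.

**Landmarks.** A stylized 7-landmark fish template (shipped as a
fixture file; unit centroid size; posterior/anterior ratio 1.6 — not
asserted as biological truth) plus a per-group displacement field plus
isotropic landmark noise, then randomly rotated, translated, and scaled
by a log-normal centroid size so alignment must undo real nuisance
transforms.  Group deformation fields are solved at run time by pulling
the posterior-only landmarks toward their polygon centroid until a
target area ratio is met: 1.6 / 1.6 / 1.5 / 1.3 for Site 1
female/male and Site 2 female/male — the sex dimorphism lives only in
Site 2.  Standard-length medians are 22 / 13 / 10 / 9 mm with the
field sample's heavier male spread (log-sd 0.50 / 0.22 / 0.30 / 0.16),
and group sizes are the field sample's 62 / 9 / 49 / 23.  The landmark
noise (sd 0.007 shape units, within-cell ratio sd ~0.10) is set
somewhat below the field sample's ratio spread (0.14–0.24): the
generator's job is to plant effects the pipeline must recover with high
probability at these cell sizes, and field-level noise would leave the
interaction test underpowered by design rather than by implementation.

What the generator does **not** emulate: real tracking dropouts and
identity swaps (detection is always perfect; the QC gate is exercised
with constructed fixtures), hydrodynamics, wall-following or zonal
social rules, photographic perspective error, and any dose–response
structure.  Passing tests therefore demonstrate that the pipeline's
computations and inferences are correct under the stated statistical
structure, not that the movement model is a faithful fish simulator.

## Test-suite problem sizes and numerical choices

Null-calibration runs use 500 replicate studies with recordings
shortened to 12 s at 10 fps (the endpoints' null distributions under
identical sites do not depend on recording length); effect-recovery
runs use 50 replicate studies at the full 180 s / 30 fps scale.
Type-I checks accept [0.02, 0.08] at alpha = 0.05; each recovery
pattern component must hold in at least 90% of replicates.

Degenerate inputs are first-class: coincident mouth/caudal landmarks
warn and return zero length; an all-coincident landmark configuration
aborts alignment naming the specimen; zero variance in both Welch
samples, all-zero paired differences, and all-identical Kruskal–Wallis
values raise degenerate-data errors rather than returning numbers.
Identical-specimen PCA flags the zero-variance case instead of
dividing by it.  Tie-broken quantities (average ranks, component
signs, consensus orientation) all have deterministic rules stated
above, so reruns with one seed are byte-identical.

## Known limitations

* Absolute exploration percentages depend on the grid cell size and do
  not reproduce any particular published mm^2 scale.
* The MANOVA F approximation (Pillai) is asymptotic; at very small
  samples prefer the per-term Pillai value itself.
* The generator's cohesion is a single centroid-spring parameter;
  recovery of richer interaction rules (alignment, zonal repulsion) is
  out of scope.
* Dataset-level numbers from the archived field data (e.g. the printed
  PC1+PC2 variance share or group means) require that dataset; the
  readers accept its documented formats, but the desk-scale suite makes
  no claim to reproduce those absolute values.
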