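# Methods

`orthoplan` implements a decision-support pipeline for dento-maxillofacial
deformities: multilabel diagnosis from cephalometric features and automated
orthognathic surgical planning by adaptive artificial bee colony (aABC)
optimization over rigid motions of the maxilla, mandible and chin.  This
note records the models, the assumptions behind them, the tunable
parameters, and the design choices made where the design was genuinely open.

## Cephalometric geometry

Landmarks are named 3D points in mm.  The patient frame is built from the
cranial base, which never moves during surgery:

- The **Frankfort horizontal plane (FHP)** is the plane through the left and
  right orbitale and the midpoint of the two porions; its normal, oriented
  toward nasion, is **+z** (superior).
- The **midsagittal plane (MSP)** passes through nasion and sella orthogonal
  to the FHP; the projection of the sella-to-nasion direction onto the FHP
  is **+y** (anterior), and **+x = y × z** points patient-left.  The origin
  is sella.

The measurement battery: SNA, SNB, SNPog (angles at nasion), ANB defined as
the signed difference SNA − SNB, occlusal-plane pitch and roll relative to
the FHP (plane through the upper-incisor midpoint and the two upper first
molar cusps; pitch positive when the plane descends anteriorly, roll
positive when the patient's left side is inferior), the bilateral ratios
Or–U6 right/left and Go–Me right/left (percent), Pog–MSP (signed lateral
chin position, patient-left positive) and N-ANS/ANS-Me (percent lower-face
proportion).  Every measurement is invariant under a global rigid motion of
the landmark set, so the frame convention is internal; this invariance is
asserted to 1e-6 in the tests.  ANB is a definition here, not an
independent 3D measurement — some clinical datasets report ANB measured
separately, which need not satisfy the identity exactly.

Reference intervals (per measurement, per sex) ship as an editable YAML
resource with standard Chinese-population adult norms; midpoints are the
planner's default targets and half-widths its normalization constants.

## Surgical plan kinematics

A plan has 15 free parameters: maxilla and mandible each take 3 Euler
rotations (degrees, extrinsic x-y-z about the segment's movement center)
plus 3 translations (mm); the chin takes a translation only.  Movement
centers follow clinical convention: upper incisor for the maxilla, lower
incisor for the mandible, pogonion for the chin.  The chin (genioplasty
segment) rides on the mandible, so its world motion is the mandibular motion
composed with the chin translation.  Cranial-base landmarks are fixed.
Terminal occlusion can be recorded as two three-point marker triplets; the
closed-form Kabsch alignment recovers the relative rigid motion and its
residual RMS, and an optional quadratic penalty couples the two jaws in the
planner (off by default, weight `occlusal_weight`).

## The aABC planner

The fitness of a candidate plan x is

F(x) = Σ_k u_k ((c_k(x) − t_k)/w_k)²  [+ λ · occlusal misfit²]

over the targeted measurements, with c_k the post-move measurement, t_k the
target (interval midpoint by default), w_k the interval half-width and u_k a
weight (default 1).  The half-width normalization makes degrees, millimetres
and percent commensurate; F = 0 iff every target is met.  The "middle of
the normal range is best" principle fixes the default targets; an expert can
override any target inside its interval (`adjust_targets` /
`PlanningResults.interact`) and re-optimize, warm-started from the previous
best plan — the human-computer interaction loop.

The search is a bee colony of `np_bees` (default 40) with `np_bees/2` food
sources, employed → onlooker → scout phases per cycle, greedy one-to-one
replacement, onlooker selection probabilities p_i ∝ 1/(1 + F_i), and
abandonment after `limit` (default 50) failed trials.  The neighborhood
move blends a differential exploration term and a global-best-guided
exploitation term componentwise:

v_j = x_j + a(c)·φ_j·(x_j − partner_j) + (1 − a(c))·ψ_j·(g_j − x_j)

with independent φ_j ~ U(−1,1), ψ_j ~ U(0,1) per dimension and the adaptive
coefficient a(c) decaying linearly from `a_start` = 1 to `a_end` = 0.5 over
`t_max` cycles (default 500).

Two design choices matter and were made deliberately after measuring the
alternatives:

- **Full-vector moves.** Perturbing a single random dimension per candidate
  (the classic ABC rule) makes every move axis-aligned; the cephalometric
  objective is strongly coupled (several measurements share each plan
  parameter), so single-dimension search degenerates into coordinate descent
  along a correlated valley and converges roughly an order of magnitude
  slower on displaced-template problems.  Componentwise full-vector moves
  keep the population-difference term aligned with the valley, the same
  mechanism that makes differential evolution effective on nonseparable
  objectives.
- **a_end = 0.5.** Letting the adaptive coefficient decay all the way to 0
  removes the differential term entirely in late cycles, leaving only a
  contraction toward the incumbent that cannot track correlated directions.
  Keeping a ≥ 0.5 preserves those steps while the exploitation weight still
  grows monotonically.  `a_end = 0` remains available in `ColonyConfig`.

Default bounds are ±8 mm translations and ±10° rotations — typical clinical
feasibility — and everything is configurable.  Determinism: one
`numpy` Generator seeded from the run seed drives initialization, partner
choice, moves and scout restarts, so a (seed, config, input) triple
reproduces the result exactly.  `grid_oracle` provides a brute-force
exhaustive argmin over up to 4 plan dimensions as an independent check on
the stochastic search.

Typical problem sizes: a default run (NP = 40, 500 cycles) evaluates 20 000
candidate plans and takes a few tens of seconds on one core; the validation
toys in the test-suite use 200 cycles (8 000 evaluations).

## Diagnosis

The six labels (maxillary/mandibular over- and under-development,
maxillary/mandibular deviation) are treated by binary relevance: one
independent binary classifier per label.  The base learner is gradient
boosted trees (XGBoost; shallow trees, depth 3, 80 rounds, learning rate
0.3) with an L2 logistic-regression alternative selectable per config.
Feature selection is forward-sequential: features are ranked by gain
importance from a full-feature fit and admitted in rank order iff they
strictly improve stratified cross-validated accuracy (ties drop the
feature); the top-ranked feature is always admitted so subsets are never
empty.  Data are split 7:3:1 into train/validation/test by
largest-remainder apportionment of the ratio.  Probability threshold is
0.5, with ties resolving positive.  Conflicting over/under predictions for
a jaw resolve to the higher probability.  Hyperparameters can be tuned with
a seeded randomized search over a declared space; budget 0 returns the
documented defaults.

Metrics follow the standard confusion-table formulas (accuracy, precision,
recall, specificity, F1) with zero-denominator cases reported as 0 and
flagged; AUC is the tie-corrected rank statistic.

## Synthetic cohort

The generator exists so every layer can be exercised with known ground
truth.  A deterministic, bilaterally symmetric template skull has a profile
inside all default reference intervals.  Deformities are simulated as rigid
motions of the surgical segments:

| condition | generating motion | magnitude (uniform) | labeled from |
|---|---|---|---|
| maxillary over/under | maxilla ±y translation | 4–7 mm | SNA outside interval |
| mandibular over/under | mandible ±y translation | 7–11 mm | SNB outside interval |
| maxillary deviation | maxilla roll rotation, random side | 3–6° | OP-FHP roll outside interval |
| mandibular deviation | mandible lateral translation, random side | 3.5–7 mm | Pog-MSP outside interval |

Magnitude lower bounds exceed the distance from the template value to the
nearest interval bound, so a zero-noise patient is always labeled
consistently with its generating class (asserted over all 36 class
combinations).  Mandibular ranges are larger than maxillary ones because
SNB is less sensitive per millimetre (the B point sits farther from
nasion).

Labels are thresholded on the **noise-free** induced measurements — the way
a clinician labels from their own measurements — while feature vectors are
computed from landmarks perturbed by isotropic Gaussian digitization noise
(SD 0.5 mm per coordinate, configurable), plus age (sex-specific normal
draws) and sex.  Features are therefore noisy while labels are exact
functions of the generating deformity; class prevalences are exact for
every seed, and the diagnostic task remains a learning problem rather than
a lookup.

Cohort composition defaults emulate a typical orthognathic population of
574 patients: maxillary development under/normal/over 35 / 36.6 / 28.4 %,
mandibular 30.5 / 24 / 45.5 %, maxillary deviation 36.2 %, mandibular
deviation 44.1 %, 35.4 % male.  Counts are exact for any n by
largest-remainder apportionment; each composition axis is shuffled
independently, so marginals are exact while joint combinations vary with
the seed.

What the generator does **not** emulate: real cohorts have continuous
severity spectra (not a normal template plus discrete motions), vertical
and combined-direction growth anomalies, correlated deformity axes
(class II/III syndromes), measurement error structure beyond isotropic
Gaussian noise, and label noise from clinical judgment.  Passing tests on
this cohort therefore validate the machinery (geometry, optimization,
selection, metrics), not clinical performance.

## Evaluation statistics

- **Plan deviation**: every evaluation point (segment member landmarks by
  default, or any supplied point cloud) is mapped under both plans; the
  per-point Euclidean distances are summarized as mean, sample SD and the
  strict-inequality fractions below 2, 3 and 4 mm.
- **Paired t**: classic paired statistic, two-sided p on n−1 df.  Identical
  samples return t = 0, p = 1; a constant nonzero difference has zero
  variance and is flagged degenerate instead of returning a number.
- **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  rater — computed from the ANOVA mean squares.  This is the standard form
  for several raters scoring the same subjects; it is ≤ 1 and equals 1 iff
  rater and residual variance vanish.
- **Score summaries**: median, mean, sample SD (single score → SD 0) and a
  1–10 histogram.

## Numerical conventions and degenerate inputs

- Angles from `arccos` of clipped normalized dot products; zero-length arms
  (< 1e-9 mm) raise a degenerate-geometry error, as do collinear FHP points,
  collinear registration triplets and vertical occlusal planes.
- Euler order is extrinsic x-y-z (pitch, roll, yaw), degrees; any
  self-consistent convention would do, this one is fixed and documented.
- Largest-remainder ties break by position order (development classes in
  under/normal/over order), making apportionment deterministic.
- Candidate plans outside the feasible box are clamped to the box.
- Forward selection with all-tied accuracies keeps only the top-ranked
  feature (strict improvement rule).

## Known limitations

- The feature schema defaults to the 10-measurement battery plus age and
  sex; clinical deployments use larger batteries, which the extensible
  profile map and configurable feature columns accommodate but the shipped
  defaults do not.
- Occlusion is not enforced as a hard constraint between the jaws; the
  optional penalty is advisory.
- No osteotomy geometry, collision detection, mesh handling or soft-tissue
  prediction; landmarks only.
- The planner optimizes a single scalarized objective; competing aesthetic
  goals would need weight adjustment or a multi-objective extension.
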