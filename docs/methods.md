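# Methods

This note records the models, conventions and numerical choices behind
`motionval`, in the spirit of a statistical package's methods appendix.
Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
reproduce.

## Coordinate frame, units, registries

Positions live in the depth-camera frame of a first-generation Kinect-class
sensor: x to the camera's right, y up, z along the optical axis away from
the sensor. The sensor itself never defines axis directions for the user,
so this is a package convention; every plane definition follows from it:

| plane    | kept axes | dropped axis |
|----------|-----------|--------------|
| coronal  | (x, y)    | z (depth)    |
| sagittal | (y, z)    | x            |
| axial    | (x, z)    | y            |

Units are fixed, not configurable: meters, seconds, degrees. The standing
registry has the sensor's full 20 joints; the seated registry is the
standing registry minus the pelvis, spine and legs (10 joints), so every
upper-limb operation applies unchanged to both.

The five-segment chain is trunk (hip_center → shoulder_center),
shoulder-line (shoulder_center → shoulder), arm (shoulder → elbow), forearm
(elbow → wrist), hand (wrist → hand). The endpoint pairs are a package
choice — the only chain consistent with naming the segments trunk,
shoulders, arm, forearm and hand — and are fixed in `skeleton.segment_chain`.

## Trajectory cleaning

Each joint's x, y, z traces are cleaned independently, in a fixed stage
order: outlier replacement → block interpolation → moving average.
Every stage preserves series length.

**Outlier replacement.** An interior sample is flagged when it falls
outside `mean ± 1.96σ` of a local window and replaced by the mean of its
two neighbours; the first and last samples lack two neighbours and are
never replaced. Where the window statistics come from is consequential:

* *literal-3-point* — mean and population σ over `(x[i−1], x[i], x[i+1])`.
  For three points the standardised deviation of any member is bounded by
  √2 ≈ 1.414 (< 1.96, attained at windows like (0, 0, 1)); with the sample
  (n−1) estimator the bound is even lower, 2/√3 ≈ 1.155. **The rule is
  therefore inert under either estimator: it can never flag anything.**
  The test suite proves this on 1,000 random series.
* *neighbors-only* (default) — mean and population σ over the two
  neighbours only. This detects isolated spikes (σ of two equal neighbours
  is 0, so any deviation of the centre is flagged) and is the reading
  consistent with replacement "by the neighbours' mean". On white noise it
  is aggressive — about half of all samples sit outside ±1.96·(half the
  neighbour spread) — which acts as an extra median-like smoother and is
  harmless for the downstream angle estimates (replacement by the neighbour
  mean is symmetric and unbiased).
* *global-series* — mean and population σ over the whole series; flags
  only gross excursions.

All three are selectable via `OutlierPolicy`; thresholds and replacements
are computed from the input series in a single simultaneous pass, so the
result does not depend on scan direction. σ is always the population
(divide-by-count) estimator; for the two-point neighbour case the choice
only rescales the threshold by a constant and is fixed here once.

**Block interpolation.** The series is partitioned into consecutive
non-overlapping blocks of 10 samples; within each full block the 8 interior
samples are replaced by the straight line joining the block's first and
last values. A trailing partial block has no endpoint pair and passes
through unchanged. The operation is a projection (applying it twice equals
applying it once). Overlapping or sliding blocks were considered and
rejected: "groups of 10 values" reads most naturally as a partition.

**Moving average.** Centred window of `window_n` samples (odd; default 5 —
at 30 fps a 0.17 s window smooths sensor noise without visibly distorting
movement at rehabilitation speeds). At the edges the window is clipped to
the series bounds (the mean of however many samples remain), which
preserves length and introduces no phase shift; a constant series passes
unchanged and outputs always stay within the input's min/max.

## Joint angles

The included angle between two segment vectors is
`Θ = arccos(P₁·P₂ / ‖P₁‖‖P₂‖)`, in degrees in [0, 180]; the normalised
inner product is clamped to [−1, 1] before `arccos` so floating-point
overshoot never produces NaN. Near 0° and 180° the arccos formulation
loses precision of order √ε ≈ 1e-6 degrees — accepted, and made visible in
the tests, rather than switched to an atan2 form, because the atan2 form
serves as the independent oracle in the test suite.

Clinical articulations are registered pairs of vector sources:

* `elbow` — arm vs forearm; `wrist` — forearm vs hand.
* `shoulder_abduction` / `shoulder_flexion` — arm measured from the
  *trunk-down* reference (hip_center − shoulder_center): an arm hanging at
  the side reads 0°, straight overhead 180°. The two names are aliases;
  the anatomical plane of the movement distinguishes abduction from
  flexion.
* `shoulder_horizontal` — arm vs shoulder-line, for horizontal
  (axial-plane) movements where the trunk-down reference projects to zero.

With a plane requested, both vectors are projected before the angle is
taken. Frames where either (projected) vector is shorter than 1e-9 m are
degenerate and marked missing (NaN), never interpolated: filling them would
fabricate clinical data.

**Trajectory summaries.** Path length is the sum of consecutive
end-effector distances (in-plane if a plane is given). Covered area is the
convex-hull area of the projected end-effector path — a deterministic,
parameter-free definition; a triangle-fan about the shoulder was considered
and documented as an alternative but not adopted. Fewer than three
distinct or collinear points give area 0 with a warning, not an error.
Range of motion is max − min of the articulation's angle series (side
inferred from the end-effector label, articulation overridable).

## Agreement and repeatability

Differences are always first argument minus second (`d = a − b`,
`u = session1 − session2`) and the convention is echoed in every report.
Limits of agreement are centred on the *mean difference*,
`d̄ ± 1.96 sd(d)` — with `sd` the sample (n−1) estimator, appropriate for
small clinical studies. The coefficient of repeatability keeps the
population n in its denominator as defined: `CR = √(Σu²/n)`, which obeys
`CR² = sd_pop(u)² + ū²` (checked algebraically on random inputs) and is
reported both in degrees and as a percent of a caller-supplied reference
range (default the 90° task). Boundary points count as inside the limits.
Zero variance collapses the limits to the mean difference — a valid result,
not an error.

## The synthetic study

The generator's defaults *are* the study conditions, chosen once:

* **Cohort**: subject statures drawn from N(1.69 m, 0.11 m); segment
  lengths scale by standard anthropometric fractions of stature (upper arm
  0.186 H, forearm 0.146 H, hand 0.108 H, trunk 0.30 H, half shoulder
  width 0.129 H). The subject stands 2 m from the sensor.
* **Sensor noise**: isotropic Gaussian, sd 0.02 m per joint coordinate —
  the middle of the 14.1–34.8 mm error band reported for this sensor
  class. Outliers are isolated single-frame displacements of
  `outlier_scale × position_sd` (default 10×) in a random direction with
  per-frame probability `outlier_rate` (default 0; the true field rates
  are unreported, so outlier settings are exercise parameters).
* **Goniometer**: truth + observer bias + N(0, 1.5°), quantised to whole
  degrees. The 1.5° observer sd is typical intra-rater variability of
  manual goniometry; combined with the sensor noise it yields
  difference sds near the ~1.8° a field study of this design reports.
* **Protocol 1** (agreement): 9 subjects × 19 static positions
  (0–180° every 10°) × both arms = 342 pairs. Method A is the goniometer
  reading; method B the full pipeline estimate — a 1 s (30-frame) static
  burst, preprocessed, coronal-plane abduction angle, median over frames
  (median for robustness to residual outliers).
* **Protocol 2** (repeatability): per subject, a 90° shoulder flexion held
  in the sagittal and in the axial plane, measured in two sessions; each
  session estimate is the 3-D angle from trunk-down plus session-level
  Gaussian noise (posture re-assumption, repositioning, lighting) of sd
  2.266° — calibrated so the session-difference dispersion is
  sd(u) = 6.28/1.96 = 3.204°, the dispersion of the field study this
  simulator emulates. In the axial variant the arm rotates horizontally,
  so its elevation from trunk-down is 90° regardless of the axial angle;
  that is exactly why the 3-D flexion articulation is the right probe for
  both variants at the 90° target.

Determinism: identical configurations and seeds give bit-identical
sequences, CSVs and tables; all child randomness derives from one
`numpy.random.Generator`.

### What the simulator does and does not emulate

It emulates smooth single-plane arm movements, Gaussian joint noise at the
sensor's error scale, sporadic gross outliers, observer-biased quantised
goniometry, between-subject anthropometric variation and between-session
variation. It does **not** emulate occlusion, soft-tissue artefact,
skeleton-fitting failures correlated over time, elbow flexion during
nominally straight-arm tasks, or depth-dependent noise anisotropy. Passing
tests therefore demonstrate the correctness and calibration of the
*computational* chain under its stated noise model — not the field accuracy
of any particular sensor.

## Problem sizes

The statistical checks use sizes chosen to make Monte-Carlo error small
relative to each tolerance: ≥10,000 pairs for the 95%-coverage
calibrations (binomial se ≈ 0.2%), 20 replicates of the 342-pair study for
bias recovery (se ≈ 0.04°), 1,000 subjects for the dispersion-recovery
check, and 200 random series per preprocessing-stage oracle comparison.

## Known limitations

* The neighbour-based outlier rule intentionally over-flags white noise
  (see above); for heavily oversampled smooth signals this is a feature,
  for sparse or discontinuous signals it would not be.
* Angle estimates at the extremes of the range (0° and 180°) fold noise
  inward (an angle cannot leave [0, 180]), biasing single-position
  estimates near the ends by a few degrees at default noise; across the
  full 0–180° ladder the two ends largely cancel, leaving a net bias below
  0.1°.
* Covered area by convex hull upper-bounds the swept area for non-convex
  paths.
* No resampling, gap-filling, Kalman/spline smoothing, ISB joint
  coordinate systems, or angular velocity/acceleration — out of scope.
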