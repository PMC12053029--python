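# Methods

`suspendkin` implements a complete marker-based 3D kinematics workflow for
suspensory (below-branch) quadrupedal walking, together with a
forward-kinematic simulator that generates study-shaped synthetic data with
known ground truth. This note documents the models, the conventions, the
numerical choices, and what the synthetic data do and do not establish.

## Coordinate system and camera model

All geometry lives in a beam-centered frame: origin at the midpoint of the
runway beam's central axis, x along the beam (fore-aft), y mediolateral, z
vertical (up). Left- and right-side camera pairs are calibrated as separate
systems and never merged; each stride is standardized so that positive x is
the animal's direction of travel. When the travel sign is negative, x and y
are flipped *together* (a 180° rotation about z), which keeps the frame
right-handed with z fixed up and makes positive y "leftward relative to
travel". Because that flip changes the sign of y, the lateral side of each
limb is re-inferred from the standardized data (sign of the trusted distal
marker's mean y) rather than taken from the metadata label.

Cameras use the classical 11-parameter direct linear transformation

    u = (L1 x + L2 y + L3 z + L4) / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8) / (L9 x + L10 y + L11 z + 1)

solved by linear least squares from ≥ 6 non-coplanar control points
(coplanarity is detected from the singular values of the centred 3D point
cloud). Triangulation stacks each observing camera's two linear equations
and solves for (x, y, z); all cameras are weighted equally. Frames seen by
fewer than two cameras are masked invalid, not errors. Lens distortion and
camera synchronization are out of scope (frames are assumed synchronous at
60 Hz).

## Trajectory smoothing

Each marker coordinate is fit with a quintic smoothing spline (FITPACK via
`scipy.interpolate.UnivariateSpline`, k = 5) over the support phase plus a
5-frame buffer on each side, never evaluated beyond the outermost valid
sample (quintic extrapolation is unbounded). The configurable tolerance
(default 0.5 cm², split equally across x/y/z) is a **hard upper bound** on
the sum over valid frames of squared residuals. Within that cap the
allowance actually requested from the fitter is `min(budget, n·σ̂²)`, where
σ̂ is a robust noise scale from third differences of the samples
(median |Δ³y| / (0.6745·√20); for white noise Δ³y ~ N(0, 20σ²), while
smooth 60 Hz limb motion contributes ~0.1 mm and the median suppresses
isolated outliers such as gap boundaries). Rationale: a spline forced to
spend the full budget on noiseless samples would *introduce* ~0.5 mm of
systematic error (~0.3–0.8° of joint angle); the data should only be
deviated from as far as their own noise warrants, and never farther than
the configured tolerance. Noiseless input is therefore reproduced to
numerical precision while noisy input still satisfies the tolerance
contract.

Occluded frames are interpolated by the fitted spline, but only if every
occlusion run inside [TD, LO] is ≤ 10% of the support duration (strictly
greater flags the stride `gap_exceeded`, which excludes it from summaries
with a logged reason — in a 60-frame support a 6-frame gap passes, a
7-frame gap does not). Stride speed is the mean over [TD, LO] of the
spline's analytic first derivative for the proximal-most marker; by default
the fore-aft (x) component in the standardized frame, i.e. locomotor
progression speed along the beam. The full 3D derivative magnitude is
available via `speed_component='3d'`; the x component is the default
because the beam is horizontal and x is standardized to the direction of
travel.

## Skin-artifact correction

Markers over the shoulder, elbow, hip and knee ride on mobile skin; the
wrist/ankle markers are trusted. Correction rebuilds each three-marker
chain distally-to-proximally, keeping the *apparent directions* between
neighbouring markers but resetting the distances to the segment lengths
measured on the anesthetized animal (ingested in cm; forelimb uses
forearm/arm, hindlimb leg/thigh):

    mid'  = distal + L_dist · û(mid_apparent  − distal)
    prox' = mid'   + L_prox · û(prox_apparent − mid')

The proximal step is anchored on the *corrected* mid position. The
procedure is idempotent, never moves the distal marker, preserves the
apparent directions, and removes exactly any marker displacement along the
segment axis; off-axis skin motion is not corrected (and limb long-axis
rotation is not estimable from these markers at all). Frames where
neighbouring markers fall within 1 mm cannot define a direction; a stride
with > 10% uncorrectable support frames is excluded. Correction operates on
smoothed positions and angles are computed from corrected positions
directly, without re-smoothing. If one side's segment lengths were not
measured, the other side's are substituted with a logged warning.

## Angles and stride events

All angles are in degrees and are evaluated exactly at the event frames
(no averaging window):

* **mid-joint angle** (elbow/knee): the interior 3D angle at the mid joint,
  180° = fully extended, range [0, 180].
* **limb protraction**: signed deviation of the limb vector (proximal-most
  → distal-most marker) from vertical in the sagittal (x–z) plane; positive
  when the distal marker is cranial to the proximal one. A limb hanging
  vertically scores 0, which matches the near-zero values expected at
  mid-stride.
* **segment abduction**: signed deviation of a segment vector from vertical
  in the coronal (y–z) plane; positive when the distal end is lateral
  (abduction), negative medial (adduction). The right side's y is negated
  so the sign convention is comparable across limbs. A true-3D (unprojected)
  angle is not used; the coronal projection matches how transverse-plane
  limb placement is reported in this literature.

Touchdown (TD) and liftoff (LO) are video-coded frame indices supplied with
the data (0-based throughout — video coders often deliver 1-based numbers;
convert on ingest). Mid-stride (MS) is detected as the frame in [TD, LO]
minimizing |x_prox − x_dist|, ties broken to the earliest frame. Angular
excursion is protraction(TD) − protraction(LO). Stride summaries are tidy
rows (one per stride, wide per event) with girdle-neutral variable names
(`midjoint_angle`, `proximal_abduction`, `distal_abduction`,
`protraction`, `excursion`); the `limb` column distinguishes elbow from
knee. Swing-phase kinematics, gait sequence metrics and forces are out of
scope.

## Statistical layer

Each response is compared across factor levels (support-phase event, limb
girdle, or species) with a mixed-effects ANCOVA: fixed factor × speed
interaction, speed always as covariate, random intercepts for individual
and for trial nested within individual (`statsmodels` `MixedLM`, REML). A
singular or non-converging fit drops the trial term with a log message.

Box–Cox is applied (with a 1 − min positivity shift) when |skewness| > 1 —
judged on residuals after removing group means, so a genuine factor effect
is not mistaken for non-normality. This operationalizes the qualitative
"transform when necessary" practice as an automatic rule; λ and the shift
are recorded and estimated marginal means are back-transformed
endpoint-wise (no smearing correction).

Fixed-effect terms are tested with Wald F statistics using residual
(n − p) denominator degrees of freedom. A Satterthwaite approximation was
considered but is not available for `MixedLM`; with the study's design
(within-stride factors, n ≈ 250 rows) the residual-df F test is close to
nominal, which the type-I calibration test verifies empirically
(rejection rate 0.05 ± 0.02 over 500 null replicates).

When the factor × speed interaction is significant (α = 0.05), factor
levels are compared at the minimum, mean and maximum of the overlapping
speed range (the intersection [max of per-level minima, min of per-level
maxima], mean over in-range observations); otherwise at the overall mean
speed. EMMs are model predictions on that grid, averaging any other
categorical factors with equal weights, with 95% t intervals. All pairwise
contrasts are Tukey-adjusted via the studentized range distribution
(`scipy.stats.studentized_range`); with two levels this reduces exactly to
the unadjusted t test. Rank-deficient contrasts are reported as
inestimable, never silently dropped.

For the two-toed sloth (*Choloepus didactylus*) comparison only published
summary elbow/knee EMMs are bundled (as tabulated constants); when no
stride-level table for that species is supplied the species contrast is
descriptive (EMM differences and CI overlap), not a refit.

## The synthetic-data generator

The simulator is first-class, tested code; it is the package's substitute
for video data, not a fixture. One support phase is generated by inverse
kinematics of a two-link chain hanging from a fixed beam contact:

* the distal marker (wrist/ankle) grips the beam and does not move;
* whole-limb protraction runs linearly (in a progress variable) between
  its TD and LO values; the mid-joint angle follows a C¹ two-piece cosine
  through its TD, mid-stride-dip and LO values, with the dip placed where
  protraction crosses zero; each segment holds a constant coronal tilt
  (abduction);
* per frame, the two segments' sagittal angles are solved (vectorized
  Newton, planar closed-form initialization, residual < 1e-13) so the
  chain reproduces the prescribed protraction and interior angle exactly;
* time is parameterized so the shoulder/hip x position advances linearly.

The per-support fore-aft advance is then fixed by the prescribed angles and
segment lengths, so a target speed and an integer 60 Hz frame count cannot
both be met exactly: the frame count is rounded and the *realized* speed
(exact by construction) is recorded in the truth. The discrepancy is below
one frame's quantum (< 0.01 m/s over the study's speed range). Mid-stride
(Δx = 0) coincides with the protraction zero crossing by construction.
Profiles whose geometry is unreachable (e.g. an interior angle above
180° − |β_dist − β_prox|, the ceiling imposed by fixed coronal tilts) raise
an infeasible-profile error; the study generator clamps its random draws
into this feasible region.

Default study conditions: 4 individuals, 44 forelimb + 40 hindlimb strides
grouped in 1–3-stride trials on random beam sides; segment lengths drawn
per individual and side from measured ranges (arm 16–18.5, forearm
16.5–18.5, thigh 9.75–12.5, leg 10–13.5 cm); speeds uniform on
0.05–0.5 m/s; forelimb profile elbow 137 → 102 → 105°, protraction
+30 → −20°, arm abduction +4.2°, forearm −18.0°; hindlimb knee
148 → 126 → 148°, protraction +21 → −38°, thigh +2.7°, leg −18.2°.
Biological variation enters as Gaussian offsets per individual (sd 2.5°),
per trial (sd 1.5°) and per stride (sd 4°, abductions at a quarter of
that). Observations are rendered through four synthetic 1920×1080 DLT
cameras (two per side: sagittal and 45° diagonal), with 0.5 px Gaussian
digitizing noise, 2% random occlusions, and 1 cm sinusoidal skin slip
(one cycle per support, random phase) applied to the shoulder/elbow and
hip/knee apparent positions *along the segment axis* before projection.
Five frames beyond TD and LO are "digitized" by linear continuation, as a
human digitizer tracks markers slightly past the support phase. All
randomness flows from one seeded generator; equal seeds give byte-identical
datasets.

What the simulator does **not** emulate: swing-phase dynamics, off-axis
skin motion (available via `skin_slip_off_axis`, default off, to
demonstrate the correction's residual error), beam compliance, lens
distortion, digitizing blunders/outliers, and correlated occlusions.
Passing tests therefore show that the pipeline recovers truth under the
stated noise model, not that real digitized video is free of these other
error sources. Along-segment slip was chosen as the default because it is
exactly the component the segment-length correction is designed to remove,
which makes the correction-efficacy experiment a sharp test of the
implementation rather than of the model's residual error.

## Numerical choices and problem sizes

* Coplanarity threshold: smallest/largest singular value < 1e-8; DLT
  denominator singular below 1e-12; coincident-marker threshold 1 mm.
* Spline evaluation clipped to the valid-sample span; fits need ≥ 6 valid
  samples (quintic order + 1).
* Mid-stride ties break to the earliest frame; `numpy.argmin` provides
  this directly.
* MixedLM optimizers are tried in the order lbfgs → powell → nm; variance
  components below 1e-10 count as singular. When a random-intercept
  variance is estimated at the zero boundary some optimizers return a
  numerically unidentified intercept (fixed-effect variances of order
  1e14); such fits are detected (non-finite or absurdly large
  fixed-effect covariance) and the next optimizer is used.
* Acceptance and test simulations use the full 84-stride study once, plus
  500 null and 100 effect-recovery replicates at the summary-table scale
  (80 strides × 3 events each), which keeps the whole suite and the
  acceptance script at a few minutes on one CPU while leaving Monte-Carlo
  error on the type-I rate at about ±0.01.

## Known limitations

* Degrees of freedom are residual-based, not Satterthwaite/Kenward–Roger;
  with very few individuals and between-individual factors the tests
  would be anti-conservative (the study's factors are within-individual).
* Back-transformed EMMs after Box–Cox are median-scale, not mean-scale.
* The correction restores segment lengths exactly but inherits any error
  in the apparent *directions* (off-axis slip, smoothing residue).
* Speed from the x component understates true 3D path speed when the
  animal's path deviates from the beam axis.
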