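# Methods

This note documents the models, conventions and numerical choices behind
`carousel`, and what the synthetic benchmark does and does not establish.

## Geometry and reference frames

Positions are stored in the room frame (origin at the arena centre, cm).
The arena frame is obtained by rotating each sample by
−(`rotation_sign`·`rotation_rate`·t + `arena_phase0`).  The rotation is
reconstructed analytically; a measured per-sample `arena_angle` column
overrides the analytic model for recordings where the arena orientation was
tracked.  Angles are counterclockwise-positive (atan2 convention) and
reported in [0, 2π).  The direction of rotation relative to this convention
is configurable (`rotation_sign`); all defaults use +1 (counterclockwise),
and results should be quoted together with the sign used.

Sector membership depends only on the polar angle.  The sector is the
half-open interval [centre − width/2, centre + width/2), so a uniform
angular sweep counts each direction exactly once; a 1e-9 rad tolerance
keeps the boundary stable under the cos/sin/atan2 round trip.  The exact
centre (angle undefined) is defined to be outside.

## Segmentation

**Stage 1** splits each session into maximal runs of out-of-sector samples:
a segment starts at the first sample after exiting the sector and ends at
the last sample before the next entrance.  Tracking gaps longer than 3
sampling intervals also break contiguity (25 Hz recordings are assumed
continuous; this guards real data).  Runs shorter than the 5 s minimum
subsegment duration are discarded — the same minimum as stage 2, applied at
both stages so that no stage-1 material too short to ever yield a valid
subsegment is carried forward.

**Stage 2** works on the angular speed about the arena centre in the
*arena* frame — the animal's true locomotion frame, and the frame in which
the kinematic features are defined.  The angular speed is the magnitude of
the finite-difference derivative (`np.gradient`) of the unwrapped polar
angle, optionally smoothed by a centred 5-sample (0.2 s) moving average to
suppress tracking jitter; samples at the exact centre inherit the previous
valid angle.  The scan accumulates samples into a subsegment; once the
subsegment is older than the 1 s warm-up its running median angular speed
is defined, and a sample deviating from that median by more than the
cut-off (default 0.6 rad/s; strict inequality, so a sample exactly at the
cut-off does not split) terminates the subsegment at the previous sample
and starts a new one with a fresh warm-up.  The running median is an
insert-only two-heap structure (O(log n) per sample); an O(n²) re-scanning
reference implementation exists in the test suite and the two agree
index-for-index on randomized segments.

The cut-off can be re-derived from data: the scan is run without splitting,
all |median − local| differences are pooled, upper outliers are identified
by the boxplot rule Q3 + 1.5·IQR, and the suggested cut-off is the midpoint
of the outlier subsample's own quartiles rounded to 0.05 rad/s.  On the
synthetic cohorts this procedure suggests a lower cut-off (≈0.35 rad/s)
than the 0.6 rad/s default because simulated locomotion is smoother than
real rat locomotion; the default is kept at 0.6 rad/s, the value
appropriate for recorded data.

## Features

Quartiles use linear interpolation between order statistics (NumPy's
default, "type 7") throughout; the logarithm is natural.  Angular
dispersion is computed on the *unwrapped* angle sequence in time order —
the raw max − min of wrapped angles is branch-cut sensitive and
uninterpretable for paths crossing ±π, and unwrapping lets multi-lap
segments report dispersions above 2π.  Log-radius statistics and centrality
are computed once each: the radius is rotation-invariant, and centrality is
defined on arena-frame arc length with chord-circle crossings apportioned
by linear interpolation.  Speed change frequency counts strict sign changes
of (speed − 0.25·median speed); samples exactly at the level attach to the
previous side, and a zero median speed yields 0.

Degenerate inputs are defined, not rejected: a perfectly balanced segment
(near-zero resultant vector) has angular distance 0; a zero-length segment
has centrality 0.

## Clustering

Features are z-scored before PCA by default (the 11 features mix radians,
cm/s and dimensionless quantities; raw PCA would be dominated by the
largest scale).  This choice is exposed as `scaling="raw"|"zscore"` because
printed variance fractions depend on it strongly.  PCA retains all
components internally (fractions sum to 1); the transform keeps the
requested leading subset.

K-means is Lloyd's algorithm run to an assignment fixed point, seeded by a
deterministic Density-K-means++ rule: point density is estimated as the
reciprocal mean distance to the ⌈√n⌉ nearest neighbours, the first seed is
the densest point, and each further seed maximises density × distance to
the chosen seeds.  There is no RNG anywhere in the default clustering path:
repeated runs are bitwise identical.  An emptied cluster is re-seeded with
the point farthest from its assigned centroid.  Cluster naming is manual by
design: the pipeline emits cluster trees (shared-member graphs across
k = 1…10 for each PC count, with adjusted-Rand stability between PC
settings) and exemplar subsegments near each centroid; only synthetic
benchmarks, where per-sample ground truth exists, auto-map clusters by
plurality truth label.

## Classification

The zoo covers linear/quadratic discriminants, Gaussian naive Bayes, k-NN
variants (1/10/50 neighbours, cosine metric, distance weighting), decision
trees of three depths, linear/quadratic/cubic/RBF SVMs, bagged and boosted
trees and a random-subspace forest — a configurable approximation of the
usual classification-app presets.  Each estimator is wrapped with a
standard scaler so feature scaling is fitted inside each CV fold (no
leakage).  Accuracy is stratified 10-fold CV, seeded; "at least 75 %" is
read as ≥ 0.75.  A candidate that cannot be fitted (e.g. a singular class
covariance on very small data) scores 0 and is never selected.  Majority
voting assigns the plurality label; any tie for the top count yields
`unidentified`.

## Group statistics

The Friedman test is implemented in closed form with tie correction
(SciPy's implementation refuses k = 2 treatments, which is exactly the
two-group design needed here); it matches SciPy for k ≥ 3 and offers an
exact within-block permutation null for small tables
(`method="exact"`).  The group comparison ranks all animals jointly within
each session, reduces to per-group mean ranks, and blocks over the five
training sessions (treatments = groups, blocks = sessions); the retrieval
session is reported in tables but excluded from tests.  With two groups and
five blocks the smallest attainable p is 0.0253 (all five sessions
concordant), which bounds the resolution of this design.  The exact
blocking behind published analyses of this task is generally not stated;
this one is documented and an animal-level table can be tested directly
via `friedman_test`.

Shock timing (for data without recorded shock flags, and for simulation):
the first pulse fires at the entry sample and further pulses every 1.5 s
while the animal stays inside; pulse duration is ignored for counting.  An
animal starting a session inside the sector counts as one entrance.
"Maximum time avoided" is the longest interval from an exit (or session
start) to the next entry (or session end).

## Synthetic cohorts

The generator emulates the study conditions: 10 animals per group, five
20-minute shock-on sessions plus one retrieval session, 25 Hz sampling,
0.3 cm isotropic Gaussian tracking jitter.  The default strategy mixes
plant the reported direction of group differences — treated animals lean on
thigmotaxis (0.40 vs 0.20) and incursion (0.25 vs 0.15), controls on
focused (0.30 vs 0.10) and avoidance (0.25 vs 0.10), chaining comparable
(0.10 vs 0.15) — constant across sessions (learning dynamics are a
non-goal; a per-session mix can be supplied).

Bout archetypes are mean-reverting (Ornstein–Uhlenbeck) constructions of
the five verbal definitions: wall-band walks (thigmotaxis), wall walks with
sinusoidal inward excursions (incursion), 2-D OU about a room-frame anchor
kept outside the sector (focused), small arena-frame jitter drifting toward
the inner arena (chaining), and arena-frame idling with room-frame angular
retreats triggered within 0.3 rad of the sector edge — retreating
immediately when a bout starts inside the danger zone (avoidance).  Bouts
start at the previous bout's endpoint and relax into their regime through
their own dynamics, which keeps positions continuous without a separate
blending step; consecutive bouts are joined by a ~0.6 s reorientation turn,
mimicking the abrupt heading change of a behavioural switch.  These turns
exceed the angular-speed cut-off, so the stage-2 scan splits at behaviour
boundaries and the short turn fragments fall below the 5 s minimum and are
discarded — subsegments are essentially pure bouts, which is what makes
per-subsegment ground truth (plurality of per-sample labels) meaningful.

What the benchmark shows: the full pipeline (segmentation → features →
PCA → K-means → plurality mapping) recovers planted strategies on ~86 % of
subsegments, and the Friedman procedure detects the planted
thigmotaxis/avoidance contrasts while staying non-significant on ≥ 90 % of
null (equal-mix) cohorts.  What it does not show: real rats do not switch
behaviours with stereotyped reorientation turns, their kinematics are
rougher (hence the data-driven cut-off differs), and real cluster
structure is less separated — on recorded data the manual inspection step
and classifier accuracies in the high-70 % range are to be expected rather
than the near-perfect synthetic separability.

Scaled problem sizes in the test suite (smaller cohorts for unit tests,
6+6 animals × 5 × 5-minute sessions for the 20-seed null batch) were chosen
to keep the suite quick while preserving the design being tested; the
full-size default cohort is exercised by the recovery benchmark and the
acceptance script.

## Known limitations

- The stage-1 discard rule (5 s minimum) is a package choice; published
  segment counts from recorded data depend on an unstated discard rule and
  may differ.
- Subsegment *count* percentages over-represent behaviours that survive
  segmentation as single long subsegments; the generator benchmark
  therefore validates planted mixes on duration-weighted shares, while the
  reported tables use counts (the field's convention).
- The two-group, five-block Friedman design cannot produce p < 0.0253;
  finer resolution requires more blocks or animal-level testing.
- No importer for proprietary acquisition formats; data must be converted
  to the documented CSV.
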