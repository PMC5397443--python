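# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data it is validated on, and the
numerical choices made where the design was genuinely open.

## Trial model and preprocessing

A trial carries multi-rate channels: proximal axial force (N) and torque
(N·mm) at 25 Hz, 3-D tip positions (mm) at 40 Hz from a 5-DoF
electromagnetic coil, or distal 3-axis contact forces (N) at 25 Hz.
Sign conventions are fixed at ingest: push > 0 / pull < 0 for axial force,
clockwise > 0 / counterclockwise < 0 for torque. Phase boundaries are two
interior times supplied with the trial (in practice they come from manual
or video-based anatomical annotation, which is outside this package's
scope); phases are half-open intervals [start, end), with the final phase
closed at the trial end so the three phases partition the span.

**Synchronization.** All channels are linearly interpolated onto one
uniform clock over their common time span. The default rate is 25 Hz —
the force-acquisition rate — because the metrics mix force and position
and the slowest stream bounds the information content; the 40 Hz EM
stream is therefore downsampled. Synchronization is idempotent: the
resampled clock regenerates itself exactly on a second pass.

**Pivot calibration.** The EM sensor origin is not the physical tip; with
the tip held on a fixed pivot c, each tracked pose (Rᵢ, pᵢ) satisfies
Rᵢt + pᵢ = c for the constant sensor-frame offset t. Stacking poses gives
the linear system [Rᵢ −I][t; c] = −pᵢ, solved by dense least squares; the
RMS of ‖Rᵢt + pᵢ − c‖ is reported as the calibration residual. At least
two distinct orientations are required (the stacked matrix is otherwise
rank-deficient, and the code raises). On 800 poses with 0.3 mm isotropic
translation noise the 3.60 mm offset is recovered to well under 0.1 mm.

**Tip-offset correction.** A 5-DoF coil has no roll, so per-sample
orientation is usually unavailable; the scalar offset is then applied
along the unit tangent of the moving-average-smoothed trajectory (window
5 samples). With full orientations available, positions are shifted by
Rᵢt. On straight trajectories the tangent form is exact and involutive;
on curved ones it is first-order accurate in the offset-to-curvature
ratio, which is adequate for a 3.6 mm offset on vascular-scale curves.

## Per-phase metrics

Derivatives are first differences on the synchronized uniform clock with
**no pre-smoothing**: no filter is part of the metric definitions, and
filtering changes maximum-speed values materially, so the default stays
transparent.

- Speed: ‖pᵢ₊₁ − pᵢ‖/Δt; acceleration: |speedᵢ₊₁ − speedᵢ|/Δt; median and
  max per phase.
- Smoothness: with sᵢ the cumulative displacement and vᵢ its slope,
  Σᵢ|vᵢ₊₁ − vᵢ|/Δt (mm/s²). Zero for constant-speed motion; each
  instantaneous speed step Δv contributes Δv/Δt. At 25–40 Hz this
  definition yields the 10⁴–10⁵ magnitudes typical of whole-phase
  recordings.
- Displacement peaks: local maxima of distance-from-start ‖pᵢ − p₀‖ with
  prominence ≥ 1 mm (above EM jitter — the pivot RMS is ~0.6 mm — and
  below retraction depths of interest). Distance-from-start is used
  because cumulative path is monotone and peak-free by construction.
- Push/pull and CW/CCW means are episode-conditional: the mean of
  positive samples and the mean magnitude of negative samples, 0 when a
  side is empty. (Whether such means should instead be taken over all
  samples is ambiguous in the field; the episode-conditional choice is
  documented here and used consistently.)
- Tip positions are used in 3-D (not a 2-D projection).

Distal metrics operate on the RMS force modulus √(Fx²+Fy²+Fz²) after
per-run baseline subtraction f − min(f) — the run minimum corresponds to
no tissue interaction, and subtracting it is the only reading of
"remove the bias" that keeps forces non-negative; it also makes the
metrics invariant to any constant sensor offset, modelling the sensor
being zeroed at procedure start. Baseline subtraction is per run, not per
phase. FIT is the trapezoidal force–time integral; phase windows for FIT
share boundary samples so phase values sum exactly to the run value,
while all other statistics use half-open windows. Contact counting is
threshold-excursion counting (rising edges above 1 N), parameter-free
beyond the threshold, with no minimum dwell time (configurable). Note
that excursion counts are monotone non-increasing in the threshold only
for burst-structured signals (separated unimodal contacts — the physical
regime); for noise-dominated signals upcrossing counts peak near the
mean level.

## DTW repeatability

Alignment uses local cost |xᵢ − yⱼ|, steps {(1,0), (0,1), (1,1)}, and a
Sakoe–Chiba band of half-width ⌈band_fraction × max(len)⌉ (default 0.1,
standard practice for warping constraints). Costs are normalized by the
warping-path length by default; otherwise the accumulated cost of a long
recording is incomparable to that of a short one. Force and torque are
aligned separately (per-signal costs, matching how repeatability is
reported per channel); joint multichannel alignment is not used, and
per-recording z-scoring is available but off by default. The reference
recording is the one whose length is closest to the mean length (ties to
the lowest index). When two repetitions differ in length by more than the
band, `average_similarity_cost` widens that pair's band to the minimum
half-width that can connect the path corners; `dtw_align` itself refuses
an infeasible band so the constraint is never silently violated. The DP
inner loop is JIT-compiled (numba) and the implementation is checked in
the tests against exhaustive enumeration of all monotone paths on series
up to length 6.

## Group statistics

Two-sided Wilcoxon rank-sum per (task, phase, metric). The null is
enumerated exactly for tie-free samples of combined size ≤ 12; otherwise
the normal approximation with tie and continuity corrections is used (the
two branches agree to < 0.02 at the boundary). Quantiles use the
linear-interpolation rule. Each trial is an independent observation —
matching the study design this package mirrors — and **no
multiple-testing correction is applied** (none was in that design);
reports state both choices prominently. Cells where both groups are a
single constant are emitted but flagged untestable rather than given a
fake p-value.

## Skill classification

Feature vectors are the whole-run baseline-subtracted modulus decimated
to n samples by index selection (sample ⌊kT/n⌋), n ∈ {32, 64, 128}; no
upsampling is permitted. The SVM uses an RBF kernel; C ∈ {2⁻⁵,…,2¹⁵} and
γ ∈ {2⁻¹⁵,…,2³} in factor-4 steps (the standard libsvm-guide grid) are
tuned by stratified k-fold CV accuracy, ties resolved to the smallest C
then smallest γ. k is not dictated by the study; the default k = 6 gives
7 trials per fold at the 42-trial task size, stratified so both classes
appear in every training split. Evaluation repeats the k-fold partition
10 times with fresh randomization, pools the fold confusions per repeat
(pooling is robust to small folds, as opposed to averaging per-fold
ratios) and computes precision/recall/accuracy with expert as the
positive class; zero-denominator measures are reported as NaN, never as
0, and means over repeats are NaN-aware. Features are z-scored per column
with statistics fit on training folds only (no leakage); raw forces span
~0–2 N, so scaling mainly conditions the RBF bandwidth search. These
evaluation choices (k, scaling, pooling) are this package's defaults,
documented as such — not inferred choices of the original analysis.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not catheter
biomechanics. Per trial: the tip moves along a fixed task-specific 3-D
polyline (≈600 mm, realistic total length for these anatomies) at a
phase-dependent base speed modulated by a smooth lognormal process with
median multiplier 1 (≈1 s correlation time), so per-phase median speed
tracks the profile's `advance_speed_mm_s`. Poisson reversal events insert
triangular retract/re-advance excursions; a single event type
simultaneously produces displacement peaks, speed/acceleration spikes and
pull-force episodes, reproducing the *coupled* group differences seen in
real operators. Axial force follows signed speed through a force gain
plus a pull bias during retraction; torque and distal contacts are sparse
half-sine events, three times denser in the cannulation phase; contact
bursts have random 3-D direction and lognormal amplitude/duration, ride
on a slow ~0.01 N baseline wander, and are quantized to the sensor's
4 mN resolution. Operator identity is a lognormal multiplier (σ = 0.15)
on the main profile parameters drawn once per operator, so repetitions
correlate within operators — required for the repeatability analysis.
All randomness flows through one generator seeded from
(design seed, operator, task, repetition) indices.

Default profiles are calibrated to the real study's printed group
medians: expert/novice phase-A median tip speed ≈ 2.2/4.1 mm/s (reported
medians 2.08/3.77 with IQRs 1.7–2.8 / 2.2–8.0), cannulation-phase maximum
contact force medians ≈ 0.50/1.81 N (reported 0.54/1.75 for the hardest
arch vessel), experts producing no contacts above 1 N. Novices also take
longer (phase durations ≈ 70/50/55 s vs 55/35/35 s).

What the generator does **not** model: vessel-wall mechanics and friction,
guidewire exchanges, fluoroscopy-guided decision making, operator
learning across repetitions, heavy-tailed speed bursts (real recordings
show maximum speeds of hundreds of mm/s against medians of a few mm/s),
and EM jitter at its raw magnitude (position noise is kept at 0.01–0.02
mm so that 25 Hz first-difference speeds reflect motion rather than
noise; real pipelines would smooth first). Consequently, passing tests
show that the *pipeline* recovers planted group structure with correct
direction and plausible magnitude — they do not certify performance on
real operator recordings, whose absolute metric values are not
reproducible here.

Null-hypothesis calibration (the false-positive-rate check) generates
cohorts where both arms share the expert profile, with **one repetition
per operator and 15 operators per arm**: under the null the test's
independence assumption must actually hold (repetitions within an
operator correlate by design), and small discrete samples make the exact
test conservative. Measured type-I error at α = 0.05 is ≈ 0.03–0.05 over
504 comparisons.

## Problem sizes and determinism

Validation runs use the study's own designs: 126 distal trials
(4 + 10 operators × 3 tasks × 3 reps), 48 proximal trials per task
(6 + 10 operators × 3 reps), 800 pivot poses, 200 random DTW oracle
instances, 14 null cohorts (504 comparisons), 10 CV repeats. DTW on
full-length recordings decimates 25 Hz signals by 5 before alignment —
the repeatability contrast is insensitive to this and alignment cost
scales quadratically. Cohorts are pure functions of (design, profiles,
seed); the pipeline bundle's tables are byte-identical across reruns of
the same configuration and seed.

## Known limitations

- Phase boundaries are inputs; no automatic segmentation.
- The scalar tip-offset correction is approximate on curved trajectories.
- DTW cost normalization (path length) is one of several conventions; raw
  costs are exposed for comparison with other tools.
- The rank-sum analysis inherits the "each trial is independent" design;
  `group_stats.loo_operator_sensitivity` recomputes every comparison with
  each operator left out (worst-case p-value, flag stability) but is off
  by default in reports.
- Classification is per task and binary; multi-class or sequence models
  (e.g. HMMs) are out of scope.
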