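# Methods

This note documents the models, conventions and numerical choices behind
`penrhythm`, and what its synthetic-data tests do and do not establish
about real tablet recordings.

## Measurement model

A trial is a 200 Hz stream of samples (t, x, y, pressure) from a digitizer
recording one written word. Pressure 0 marks pen-in-air samples; any
positive pressure counts as pen-down (the raw magnitude is preserved but
not otherwise used). Positions are in cm, time in seconds; a dialect
config rescales device units on read. Coordinates follow y-up with the
origin at the tablet's lower left; all derived quantities use differences
only, so the convention matters only to the simulator.

## Segmentation

* **Strokes** are maximal runs of pen-down samples. Runs shorter than
  40 ms are discarded as artifacts (pen bounces, spurious contacts). Both
  thresholds are strict, with a 1 ns float-subtraction guard so that
  exactly-threshold durations computed on a sampling grid are not
  misclassified.
* **Words**: consecutive strokes separated by an in-air gap of at most 5 s
  belong to one word; a longer detachment ends it.
* **Letters.** For block capitals, where letters are separate stroke
  clusters, strokes are clustered temporally: the n−1 largest inter-stroke
  gaps are the letter boundaries. For cursive, where the word is typically
  one continuous stroke, boundaries are placed at strict local minima of
  the smoothed speed profile: the candidates are ranked by speed, and the
  n−1 lowest minima are chosen subject to every resulting letter lasting
  at least 50 ms (`letter_min_duration`), ties broken by earlier time. The
  rationale is that inter-letter transitions are the slowest points of the
  trace (high curvature → low speed under the speed–curvature power law),
  and the duration guard prevents degenerate slivers when a letter
  contains several shallow minima.
* When fewer qualifying minima exist than boundaries needed, segmentation
  fails with an instruction to supply a per-trial **override file**
  (trial_id, letter_index, boundary_sample_index) — the programmatic
  equivalent of an experimenter's manual correction. Overridden trials are
  marked `source="override"`.
* Letter spans are consecutive and inclusive; the boundary sample starts
  the next letter. A letter's duration counts pen-down time only, summed
  over sample intervals, so letter durations partition the word's pen-down
  duration exactly.

## Kinematic quantities

* Speed is the magnitude of the first derivative of (x, y) with respect to
  t, central differences inside, one-sided at the ends. Before
  differentiation, coordinates pass a zero-phase 4th-order Butterworth
  low-pass at 10 Hz (configurable, recorded in outputs): handwriting
  energy lies below ~10 Hz, and at 200 Hz sampling the quantization noise
  above it would dominate the derivative. Traces too short to filter
  stably are differentiated raw.
* Word duration **T** sums stroke durations (contact time only); length
  **L** sums straight-chord distances between consecutive pen-down samples
  (no re-interpolation: at 200 Hz the discretization error is small
  relative to the device's ±0.25 mm accuracy); mean velocity **V** is
  L/T by default. An alternative definition — the mean of per-sample
  pen-down speeds — is selectable, because published velocity regressions
  are not always consistent with the algebraic identity V = L/T implies
  (under that identity, slope(ln V ~ ln L) = 1 − slope(ln T ~ ln L)
  exactly; the package asserts this identity for its own output).
* Relative letter duration ρᵢ = 100·tᵢ/T. The ρ profile is invariant
  under joint time scaling of the word, which is precisely the Homothety
  hypothesis.

## Homothety statistics

The design is split-plot: grade Group (5 levels) between participants,
Condition (Spontaneous, Big, Fast) and Letter (5 levels) within. Small and
Slow trials are excluded upstream; participants missing any analyzed
condition × letter cell are excluded listwise.

The ANOVA is computed stratum by stratum. Each participant's 3×5 cell
matrix is projected onto orthonormal (Helmert) contrast bases; because the
basis is orthonormal, squared projections equal classical sums of squares,
and each within-stratum reduces to a one-way between-groups layout on the
projected scores. With unequal group sizes, within-effect tests use the
unweighted grand mean and Group terms the weighted between-groups SS
(Type III conventions, matching standard GLM software); in a balanced
design everything reduces to the textbook formulas, which is how the test
suite cross-checks the implementation. No sphericity correction is applied
by default — the target df structure is the uncorrected one — and
Greenhouse–Geisser is deliberately not claimed.

Because ρ is normalized (sums to 100 within each participant × condition),
the Group and Condition main-effect strata carry literally zero variance;
they are reported with `testable=False` rather than silently dropped.

Post-hoc comparisons for an interaction compare the levels of its first
factor pairwise within each level of the second (e.g. 3 condition pairs ×
5 letters = 15 comparisons for Condition × Letter), using a t statistic
built on that stratum's pooled error term; Bonferroni adjustment
multiplies by the family size and caps at 1. Defining the family as these
within-level comparisons (rather than all cell pairs) matches how such
interactions are conventionally followed up.

Partial eta squared is SS_effect/(SS_effect+SS_error), equal to
F·df_num/(F·df_num+df_den) — both identities are asserted in tests.

## Isochrony statistics

Ordinary least squares of ln T (and ln V) on ln L, pooled over groups and
the three analyzed conditions, plus one fit per group; r is the Pearson
correlation of the logs. Before fitting, a single-pass leave-one-out
screen predicts each pair's ln-duration from an OLS fit on all *other*
pairs and substitutes values whose residual magnitude strictly exceeds 4
natural-log units by the predicted value itself. Leave-one-out is the
closest literal reading of "the expected value computed on the basis of
the remaining pairs"; a single pass over the original data avoids the
ambiguity of iterated re-screening. The velocity regression reuses the
substituted dataset. Per-group correlation coefficients are compared with
Fisher's r-to-z test for independent samples — the standard test for this
situation. The scaling operation `length_ratio ** slope` converts a fitted
exponent into the duration fold change for any size manipulation.

## Synthetic traces

The generator emulates the structure of a tablet study — per-participant
size and tempo dispositions, condition instructions, 200 Hz sampling with
a pressure channel — with full ground truth. Per trial:

1. The word's spatial path is assembled from abstract letterforms at the
   condition's size scale times the participant's size effect. Cursive
   letters are **semicircular lobes** (constant curvature) joined by sharp
   connector bumps at the baseline; block letters are 1–3 separate
   polyline strokes with pen lifts in between (60 ms within, 150 ms
   between letters). The constant-curvature bodies are a deliberate
   choice: interior strict speed minima then occur only at the connectors,
   making the velocity-minimum boundary rule well-posed. The forms carry
   realistic stroke structure but are not typographically faithful — the
   analyses depend only on timing and length.
2. Total pen-down duration is drawn as T = c·L^β·exp(ε)·tempo, with
   lognormal noise ε and the tempo multiplier of the condition and
   participant. Defaults: β = 0.30, c = 1.5 s·cm⁻⁰·³ (≈3 s for a 10 cm
   word), σ_T = 0.15, Big doubles size, Small halves it, Fast multiplies
   duration by 0.7, Slow by 1.6, per-participant lognormal size/tempo
   effects with σ = 0.15. These are engineering choices for a plausible
   primary-school cohort, not estimates of any real population.
3. T is divided among letters by the target rhythm profile ρ* (plus
   optional jitter, renormalized). The default ρ* = (18, 22.5, 21.5,
   21.5, 16.5) equals the cursive template's natural time shares under
   the speed–curvature law, so the zero-noise speed profile is continuous
   at letter boundaries; a strongly mismatched profile would introduce
   speed steps there and shift the detected minima by a few samples.
4. Within each letter, time follows speed ∝ (curvature + 10⁻³)^(−gain/3) —
   the tangential form of the two-thirds power law, blended toward uniform
   speed by `two_thirds_gain` (default 1) — then rescaled so the letter
   hits its allocated duration exactly.
5. The path is resampled on the exact 1/200 s grid. Every pen-down
   segment's start and end are snapped to that grid, so durations measured
   from the emitted samples equal the allocated ones exactly; the realized
   ρ therefore matches ρ* to within one sample of quantization, which is
   the tolerance the tests use.
6. Positional jitter (default SD 0.02 cm) is **band-limited at 6 Hz**.
   Digitizer error is a slowly varying spatial distortion; white noise at
   the full sampling rate would inflate chord-summed path lengths by a
   factor of ~2.5, which no real device does. Even band-limited jitter
   adds a small length inflation that grows with samples-per-cm, i.e. with
   writing time — so end-to-end slope estimates carry a small positive
   bias under jitter, acknowledged where the tests measure recovery.

`inject_violation` produces cohorts that break one principle: a Homothety
violation shifts the first letter's ρ* in the Fast condition by a given
number of percentage points (renormalized); an Isochrony violation
flattens the exponent to β(1−m) while pivoting at a 10 cm reference length
so overall tempo and the length distribution are unchanged.

Seeding: one root seed; per-participant effects and per-trial streams are
derived deterministically from (seed, participant, script, condition), so
any trial is reproducible in isolation and cohorts are bit-stable.

A profile-level sampler (`simulate_homothety_profiles`) draws ρ tables
directly — per-participant letter preferences plus trial jitter,
renormalized — without rendering traces. Calibration and power studies of
the ANOVA use it; rendering thousands of trials would add nothing the
ANOVA can see.

## What the tests show — and what they don't

The simulator shares its *structure* with real tablet data (sampling,
pressure channel, condition layout, power-law and rhythm structure) but
not its content: real letterforms, pressure dynamics, in-air trajectories,
hesitations, and children's motor variability are all absent or idealized.
Passing tests therefore establish that the pipeline recovers known
structure correctly and that the statistics are calibrated — not that any
specific empirical result holds for real children. Published per-study
quantities (regression intercepts/slopes on real cohorts, specific F
values) depend on the recorded data and are out of scope here.

Two subtleties the synthetic experiments make explicit:

* The pooled cross-sectional duration–length slope estimates β only when
  duration variation beyond the power law is independent of length. The
  Fast instruction violates this (shorter durations at unchanged length),
  so under the full condition design the pooled slope exceeds the
  generating β; the estimator-recovery suites therefore either sample
  (L, T) pairs directly from the law or neutralize tempo multipliers.
* Cursive boundary recovery is exact to ≤2 samples only at zero noise;
  with default jitter, occasional boundaries move by tens of milliseconds,
  which mirrors why the original manual-correction step (here: the
  override file) exists for cursive.

## Problem sizes

Default test problem sizes: segmentation oracles on 400-sample traces
(200 randomized draws); ANOVA calibration on 500 cohorts of 20
participants; power at the full 298-participant shape (25 cohorts);
exponent recovery over 200 replicates of 100 pairs per β; end-to-end
cohorts of 20 participants (200 trials). The df-structure checks run the
full 298-participant table. These sizes give stable statistical checks
while keeping the whole suite near ten seconds.
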