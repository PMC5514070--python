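# penrhythm

Rhythm analysis of handwriting recorded on a digitizing tablet.

Handwriting movement is organized in time by two classical principles of
motor control. **Homothety** says that the *relative* durations of the
sub-units of a movement — here, the letters of a word — stay constant when
the word is written bigger, smaller, faster or slower: the word keeps its
rhythm. **Isochrony** says that pen speed scales with trajectory length so
that total duration stays roughly constant; operationally, word duration
*T* follows a power law in trace length *L*,

```
ln T = a + b · ln L          (b « 1)
```

so a fitted exponent of b ≈ 0.30 means a 20-fold increase in trace length
costs only 20^0.30 ≈ 2.5 times the writing time. `penrhythm` implements the
full analysis chain used in developmental graphonomics studies of these
principles, for researchers working with tablet recordings of children (or
adults) writing a target word under size/tempo instructions:

* **trace_io** — delimited-text pen traces (t, x, y, pressure at a nominal
  200 Hz) with a sidecar trial manifest; validation and lossless round trips.
* **segmentation** — pen-down strokes (pressure > 0; runs shorter than
  40 ms dropped as artifacts), word grouping (an in-air detachment longer
  than 5 s ends the word), and letter boundaries at local minima of the pen
  speed in the transitions between letters (cursive) or at pen lifts
  (block capitals), with a per-trial override file replacing manual
  correction.
* **kinematics** — smoothed speed profiles; word duration *T* (pen-down
  contact time only), length *L* (chord-summed stroke path), mean velocity
  *V* = L/T, and relative letter durations ρᵢ = 100·tᵢ/T.
* **homothety** — split-plot mixed ANOVA on ρ with grade Group between
  participants and Condition × Letter within, Bonferroni post-hocs and
  partial eta squared.
* **isochrony** — natural-log regressions of duration and velocity on
  length, pooled and per group, with a leave-one-out 4-log-unit outlier
  substitution and Fisher r-to-z comparisons of per-group correlations.
* **synthetic** — a 200 Hz trace generator with controlled Homothety /
  Isochrony structure, two-thirds-power-law timing (speed ∝ curvature^-1/3)
  and complete ground truth, so every stage is testable without real data.
* **pipeline / cli** — end-to-end orchestration (`penrhythm simulate`,
  `segment`, `analyze`, `report`) producing JSON + CSV reports; block and
  cursive scripts are always analyzed separately.

## Worked example

Simulate a 20-participant cohort (4 per grade group, every participant
writes the five-letter word once per script × condition) and run the full
analysis:

```python
from penrhythm import (SyntheticConfig, simulate_cohort,
                       PipelineConfig, run_pipeline, isochrony_scaling)

cfg = SyntheticConfig(group_sizes=(4, 4, 4, 4, 4), seed=7)
traces, truths, manifest = simulate_cohort(cfg)
report = run_pipeline(PipelineConfig(out_dir="out", seed=7), traces=traces)

blk = report["scripts"]["block"]
print(blk["counts"]["analyzed"])                 # 60
print(blk["isochrony"]["duration_vs_length"])    # intercept -0.259, slope 0.496, r 0.538, n 60
print(blk["isochrony"]["velocity_vs_length"])    # intercept  0.259, slope 0.504, r 0.544, n 60
print(round(isochrony_scaling(20, 0.496), 2))    # 4.41
```

60 of the 100 block-script trials enter the statistics (the Small and Slow
conditions are recorded but excluded, as they are unreliable to segment at
tablet resolution). The duration regression says doubling trace length
multiplies writing time by 2^0.496 ≈ 1.4 — strong duration compensation.
The two regressions are algebraically locked under V = L/T (slopes sum to
1, intercepts negate), a built-in consistency check. Note the pooled
cross-sectional slope exceeds the generating exponent (0.30) because the
Fast instruction shortens duration at unchanged length; see
`docs/methods.md`.

The Homothety table for the same run,

```
Condition x Letter: F(8, 120) = 1.03, p = 0.417, eta_p2 = 0.064
```

correctly fails to reject: this cohort was generated with the rhythm
profile identical across conditions. Injecting a distortion with
`inject_violation(cfg, "homothety", 3.0)` (the Fast condition shifts the
first letter's share by 3 percentage points) makes the same test reject in
>90% of cohorts at the study's full sample size.

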