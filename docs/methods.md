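# Methods

This note documents the models, conventions, and design choices behind the
package, and what the simulator does and does not emulate.

## Assessment protocol and trail generation

The protocol is fixed in structure: `motor_pre` (2 standard repetitions),
four core levels (`number_letter`, `exercise`, `go_no_go`, `stroop`; 4
repetitions each: standard first, then a seeded permutation of standard /
auditory / scramble), and `motor_post` (2 standard repetitions) — 20
repetitions total. Twelve characters are displayed per repetition (two
cycles of `1-A-2-B-3-C`); on the response-inhibition levels 4 of the 12 are
distractors shown in the level's no-go color (go/no-go: red distractors
among green targets; Stroop the reverse), leaving 8 correct selections.
The 8-selection count is derived from the distance standard (30 m at
~3.75 m per selection) rather than stated anywhere explicitly.

**Layout.** Only distances are standardized by the assessment, not room
shape, so the default layout is a package convention: six tablets on a
semicircular arc of radius 3.1 m centered on the start position. The radius
was chosen so a uniformly random no-repeat walk over the tablets averages
close to 3.75 m per hop, which makes both distance targets reachable by
rejection sampling with acceptance probabilities around 5%. Layouts are
fully configurable (YAML) and all distances are planar Euclidean.

**Trail search.** Character-to-tablet assignments are drawn uniformly with
the single constraint that consecutive correct selections sit on distinct
tablets; a draw is accepted when the correct-path length (start position to
first tablet, then tablet to tablet) is within the target ± 1%. The search
is bounded at 10,000 proposals and reports the best achieved distance on
failure. In practice ~15–30 proposals suffice per trail.

**Scramble.** The scramble trigger defaults to halfway through the trail
(after the 6th of 12 correct selections, or the 4th of 8). All displayed
items after the trigger are re-drawn; the relocation must change at least
one correct item's tablet (an identity permutation is rejected) and the
full-path distance is re-validated against the same window, so scramble
repetitions remain distance-standardized. Character order never changes.

**Exercise trigger.** One beep per exercise repetition, placed uniformly at
random among interior correct selections (configurable).

## Session logs and timing

Sessions are single JSON documents (schema `r2play-session/1`) with
canonical key order, so write → read → write is byte-identical; the HR
stream can live inline or in a `t_s,bpm` sidecar CSV. Timestamps are
seconds from session start. Validation returns violations as data (one
entry per broken invariant, naming its location) rather than raising.

**Active windows** are repetition spans extended by a 10 s post-repetition
tail, merged when they overlap. **Duration breakdown** reports
configuration time (the explicit configuration interval), active time, and
their sum, in minutes to 2 decimals. Active time is defined by convention,
since level orientation and rest breaks blur the boundary: the default
(`span`) measures first-repetition start to last-repetition end minus
explicitly marked break intervals (clipped to that span); the alternative
(`sum`) counts only repetition spans. Missing HR coverage for a repetition
leaves HR-dependent metrics undefined; nothing is imputed.

## Scoring conventions

* Seconds per tablet excludes exercise-beep pauses by default (the metric
  should reflect trail speed, not exercise time); pause inclusion is a
  configuration option.
* The best-of-two rule takes the minimum per metric independently across
  duplicated repetitions (shortest time, fewest errors, lowest average HR).
* The auditory/scramble baseline is the unweighted mean over the four core
  levels of the per-level standard best (best-of-two first, then mean);
  the challenge value is the unweighted mean of the per-level condition
  repetition.
* HR costs use the time-weighted (trapezoidal) average HR over the
  repetition span only — the 10 s active tail belongs to exertion
  summaries, not to per-repetition metrics.
* A zero baseline yields `undefined(zero_baseline)`; a missing level
  `undefined(missing_level)`; absent HR coverage `undefined(missing_hr)`.
  Undefined values serialize as `null` + reason in JSON and empty cell +
  reason column in CSV.
* Cohort summaries use sample SD (n − 1), the normal-approximation 95% CI
  `mean ± 1.96·SD/√n`, midpoint medians, and linear-interpolation quartiles
  by default (Tukey hinges optional). Reported values are rounded half-up
  to 2 decimals; internal math is full precision.

## Clinical measures

Age-predicted maximal HR uses the Tanaka equation `208 − 0.7·age`,
accepted for ages 5–80. Exertion percentages are `100·HR/HRmax`. SUS
polarity follows Brooke's instrument (odd items contribute `response − 1`,
even items `5 − response`), an external convention adopted because the
0–4 contribution rule alone does not fix polarity; bands are < 68 below
average, 68–80 average-to-good, ≥ 80 good-to-excellent. The symptom stop
rule fires on the first check-in response of 4; response 3 sets a
non-stopping "worsened" flag. Baseline PCSI is stored as a precomputed
total; item-level administration is out of scope.

## Simulator

The simulator exists to make the scoring pipeline testable end-to-end and
to demonstrate that injected effects are recovered by the cost scores.

* **Tap timing** is lognormal per correct selection (positive,
  right-skewed, CV-parameterized) with mean `base_spt × Π(factors)`.
  Intervals are apportioned across trail segments in proportion to segment
  distance and normalized so the repetition total is exact in expectation;
  at `noise_cv = 0` every repetition's seconds-per-tablet equals its
  planned mean exactly, which makes recovery exact in the noise-free
  limit. Condition factors apply to the whole repetition (not only
  post-trigger), so an injected factor `f` corresponds to a time cost of
  exactly `100·(f − 1)`.
* **Default effect factors** (exercise 0.93, go/no-go 0.97, Stroop 1.20,
  auditory 1.09, scramble 1.21, motor-post 0.88) emulate the behavior
  observed in the healthy pilot cohort, including the speed-ups on the
  exercise and post motor trails; they are not the hypothesized all-positive
  loading. Per-tap `noise_cv` defaults to 0.10, a plausible within-subject
  timing variability for this kind of task.
* **Heart rate** follows first-order exponential relaxation toward
  level-dependent targets `rest + intensity·(HRmax − rest)` with time
  constant 30 s (a standard exercise-physiology approximation), sampled at
  1 Hz with small Gaussian jitter, clamped to [rest, 0.98·HRmax]. Exercise
  bouts add +0.10 intensity during the pause. Between repetitions the
  target decays toward a mildly elevated recovery level.
* **Errors** occur per correct selection with probability
  `base rate × challenge multiplier` (default base 1%), so healthy
  cohorts rarely produce errors and error-based costs are usually
  undefined — mirroring the observed outcome.
* **Timeline defaults** (level orientation 150 s, repetition breaks 45 s,
  check-in gaps 60 s, configuration ~6 min) give total sessions in the
  30–40 minute range typical of supervised administration.
* **Cohorts** draw ages uniformly over 10–22, baseline speed 1.3–2.1
  s/tablet, resting HR 60–80 bpm, steady-state intensity 0.55–0.70, with a
  10% wheelchair-user rate carried as a metadata flag only.

**What the simulator does not emulate:** concussed performance profiles
(no in-scope data exists to calibrate them), speed–accuracy trade-offs,
learning across repetitions beyond the fixed factors, biomechanical
differences for wheelchair users, and HR artifacts other than complete
stream loss. Passing recovery tests therefore show that the scoring
pipeline measures what the generative model injects — not that real
athletes behave like the model.

## Problem sizes and numerical choices

Property tests use 1,000 generated trails (500 per distance target) and
parameter-recovery cohorts of 200 sessions at `noise_cv = 0.05`, with a
±2-percentage-point band on recovered medians and ±1.5 on null medians.
The small residual positive bias (~1%) in the auditory/scramble null
medians is expected: their baseline is a best-of-two minimum while the
challenge is a single repetition, so the baseline is biased slightly low
at finite noise; the symmetric level-to-level costs have no such bias.
Seeds thread through `numpy.random.SeedSequence` spawning, so cohorts are
reproducible and per-session streams independent.

## Pilot reference data

`r2play.pilot_data` carries the per-participant values recorded in the
prototype's ten-youth pilot (exertion rows, session durations, and the
worked cost-score inputs). They anchor regression tests: cohort summaries
recompute the published mean/median rows from the raw per-participant
values. The pilot's published active/total duration medians are
inconsistent with the table's own rows, so only the configuration-time
median is pinned; likewise the pilot's RPE SD matches a population-SD
convention while its HR SDs match sample SD — this package uses sample SD
everywhere and does not replicate that inconsistency.
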