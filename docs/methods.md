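# Methods

## The estimation model

The estimator assumes a conventional (non-shift-work) sleeper whose phone
is the last thing used before sleep and the first thing used after
waking. Sleep is therefore visible in the event stream as a long
no-interaction gap between a screen-off in the evening and a screen-on in
the morning. Two deliberately separated stages implement this:

**Stage 1 — permissive enumeration.** Every consecutive-session gap of at
least `min_gap` (240 min) is a candidate. The threshold is inclusive
(`≥`). The stage also repairs one systematic confusion: a brief mid-night
phone check splits the true night into two gaps, of which the morning one
starts at the check's screen-off. When the session closing a candidate's
start is part of a *short interaction cluster* — sessions chained
transitively whenever each spans less than `cluster_radius` (5 min) and
consecutive events are less than `cluster_radius` apart — and an earlier
screen-off exists at least `lookback` (120 min) before the cluster inside
the same night window, the start is walked back to that screen-off and the
cluster becomes an in-episode break. The walk iterates to a fixpoint, so
several checks per night are absorbed; with a single check it reduces to
one step. A lone sub-5-min session triggers the rule just as a multi-event
cluster does. Refinement never moves a candidate's end and never shortens
its span.

Both a gross duration (end − start) and a net duration (gross minus break
time) are carried; the package compares *net* duration to ground truth,
mirroring how actigraphy reduces a night's total by its interruptions.

**Stage 2 — scoring.** Three unit-interval factors,
`exp(−distance/τ)` each, compare (a) the candidate's start to a fixed
22:00 bedtime anchor, (b) its end to the user's habitual wake time for
that day type, and (c) its net duration to 480 min. Distances for (a) and
(b) are circular on the 24-h clock (21:00 and 23:00 are equidistant from
22:00); 480 min is the midpoint of the recommended 420–540 min band for
healthy adults. The exponential form is smooth, strictly monotone and
bounded in (0, 1], and makes the product combination a log-additive
penalty; τ = 120 min for all three factors, the same scale as the
refinement lookback. All three constants are configurable
(`ScorerConfig`). Ties in the product break toward the larger net
duration, then the earlier start.

**Night windows and day types.** Nights are noon-to-noon windows (noon is
maximally distant from typical overnight sleep); a window is labelled by
its closing date, i.e. the wake date, and a night is a weekend night when
its wake date is Saturday or Sunday.

**Habitual wake estimation.** The wake norm is learned from the log being
analysed, so it is bootstrapped: the end of the longest refined candidate
in each window seeds a provisional profile, episodes are selected with it,
and the profile is re-estimated once from the selected ends before a final
selection pass. The estimator of the norm is the circular median
(observations unwrapped around their circular mean, ordinary median taken,
wrapped back), which is robust to occasional grossly wrong nights and
handles wake times straddling midnight. Fallbacks: a day type with no
observations borrows the pooled observations; an empty log defaults to
08:00. On regular simulated sleepers the refinement pass is a fixpoint —
it changes the selection on zero nights (asserted in the tests).

## Ground-truth model

The reference device is a wrist actigraph that labels the night as
contiguous segments of `sleep`, `interruption` (awake briefly) and
`unknown` (physiology unreadable). Consolidation merges segments into
episodes: an interruption shorter than 15 min between two sleeps keeps one
episode and is subtracted from the net duration; an unknown segment
shorter than 15 min between two sleeps counts fully as sleep; either kind
at 15 min or longer (the "less than 15 min" rule is strict) splits the
night, and the longest resulting episode is the night's ground truth.

## The simulator

`sample_user_days` draws, per night: bedtime and wake time (normal,
truncated at ±3 SD to avoid day inversions, wake means day-type aware), a
pre-sleep interaction ending an exponential gap before sleep onset, a
post-wake interaction starting an exponential gap after wake, Poisson
daytime sessions with lognormal lengths, an optional 1–5 min mid-night
check, and ground-truth segments. Outputs are bit-identical for identical
(profile, days, seed).

Two presets encode the engagement contrast the estimator is sensitive to
(all values configurable; they are calibration choices, not measurements):

| parameter | student | working_mother |
|---|---|---|
| bedtime | 23:30 ± 45 min | 23:00 ± 60 min |
| wake weekday / weekend | 07:00 ± 30 / 08:30 ± 45 | 06:30 ± 30 / 07:30 ± 60 |
| pre-sleep / post-wake gap (exp mean) | 10 / 10 min | 45 / 60 min |
| daytime sessions per hour | 2.0 | 0.8 |
| night-check probability | 0.3 | 0.15 |
| interruption probability | 0.2 | 0.15 |

Design choices worth recording:

* **Night-check timing.** A check, when it occurs, is placed uniformly in
  the part of the night at least 2 h after sleep onset and at least 4 h
  before wake — the pattern of a brief awakening after the first sleep
  cycles with the consolidated block still to come, which is exactly the
  behaviour the refinement rule targets. Checks in the final four hours of
  a night would instead truncate the estimate at the check (the algorithm
  only ever walks bedtimes backward); that failure mode is real and is
  listed under limitations, but it is not what the preset's
  `night_check_prob` is meant to model.
* **Check/interruption coupling.** A phone check also writes an
  interruption into the ground truth over the same interval — the wearer
  was demonstrably awake. Additional phone-free interruptions and unknown
  segments are sampled independently (lognormal lengths, medians 5 and
  8 min), so a tail draw ≥ 15 min occasionally splits a truth night.
* **Boundary guards.** The pre-sleep interaction is forced to span at
  least 6 min so the generator never fabricates a bedtime that is itself a
  night-check cluster; boundary gaps are capped at 6 h so sessions of
  adjacent days cannot overlap.

What the simulator does *not* emulate: shift-work or free-running sleep
schedules, naps as labelled episodes, physiological signals, device
non-wear beyond the unknown-segment mechanism, and — importantly —
reference-device bias. The simulated ground truth *is* the true sleep, so
estimated start is never later than true start and estimated end never
earlier than true end; real actigraphy has boundary errors of both signs
that partially cancel in the duration. Passing simulation error levels
therefore say how the algorithm degrades with engagement structure, not
what its error would be against a particular wearable.

## Evaluation

Estimates and truth are inner-joined on wake date (duplicates are a hard
error; unmatched nights are counted and excluded). Metrics are absolute:
duration error in minutes and as a percentage of the *reference* duration,
start and end differences in minutes; aggregates are arithmetic mean and
sample SD (n−1) over all/weekday/weekend strata. The paired one-tailed
*t* test is taken on per-night `estimate − truth` durations with the tail
in the direction of the observed mean difference; p > 0.05 reads
"adequate", and an over/under direction is reported only when significant.
All-zero differences use the t → 0 limit (p = 0.5, adequate) rather than
an undefined statistic. Mean durations classify as sleep-deprived below
420 min and long above 540 min, boundaries inclusive into adequate.

## Problem sizes and numerical notes

The shipped evaluation runs use 150 days × 5 runs for the student preset
and 45 days × 5 runs for the working-mother preset (about one thousand
nights total, a few seconds on one CPU), matching the scale of the
longitudinal setting they emulate. Timestamps are timezone-aware and
compared on the absolute line; all time-of-day logic uses the wall clock
carried by each timestamp's own offset. Scores are strictly positive, so
a product of three factors never underflows to an exact tie for realistic
inputs; the deterministic tie-break exists for degenerate constructed
cases.

## Known limitations

* Low-engagement users break the core assumption: with mean boundary gaps
  of 45 + 60 min the duration is overestimated by ~100 min on average and
  the relative error sits near 20–25%, far above high-engagement levels.
* A phone check within four hours of final waking truncates the estimate
  at the check; only the bedtime side is ever repaired.
* One episode per night window: split nights yield the dominant fragment
  matched against the longest ground-truth episode.
* The 22:00 anchor hard-codes conventional night sleep; shift workers
  would need a per-user anchor.
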