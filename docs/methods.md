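# Methods

## Session model

A session is a time-ordered stream of nose pokes in two wells, one
**active** (schedule-bearing) and one **inactive** (control). The state
machine applies three rules:

1. **Counting.** A poke outside any timeout window is *counted*. A counted
   active poke advances progress toward the current response requirement;
   when progress reaches the requirement a reward is emitted at that poke's
   time, progress resets, and the requirement is recomputed from the
   schedule. Counted inactive pokes are logged but never advance the
   schedule.
2. **Timeout.** Every counted active poke (rewarded or not) opens a timeout
   window `(t, t + timeout]`, default 1 s. Pokes in either well inside an
   open window are logged with `in_timeout=True`, are not counted, and do
   not extend the window. Inactive pokes never open windows.
3. **Termination.** The session ends at `min(max_duration, time of reward
   #max_rewards)`; later pokes are discarded. The 50-reinforcement cap is
   applied to FR1 sessions only (where the protocol that motivated this
   package states it); FR5 and PR sessions run the full 60 minutes.

Timeout pokes are retained in the log rather than dropped: they are
physical pokes, and per-session "total pokes" metrics include them (with a
separate tally), so downstream analysis can make either choice.

### Numerical choices

- All times are converted once, on entry, to integer milliseconds (round
  half up). Every subsequent comparison is integer arithmetic, so replaying
  a logged stream reproduces the log bit for bit, and the CSV round trip is
  the identity.
- The timeout window is upper-closed: a poke exactly at `t + timeout` is
  still blocked. Equal-time pokes are ordered by input position; the second
  of a tie is treated as infinitesimally later (hence inside a window the
  first one opened, including at timeout 0).
- The PR requirement rounds half away from zero. Rounding (not floor) is
  the only reading of the requirement formula consistent with its published
  series (5e^0.2·5 − 5 = 8.59 must give 9); half-integer values cannot
  arise from the default constants, so the tie rule is a determinism
  guarantee, not a behavioral one. Requirements are clamped to ≥ 1 to keep
  nonstandard constants safe.

## Progression criteria

- **FR1 acquisition**: ≥ 3:1 active:inactive ratio **and** ≥ 20
  reinforcements, on 3 consecutive days; the acquisition day is the third
  passing day. Mice not acquiring by day 17 are excluded. A session with
  active pokes and zero inactive pokes has ratio +∞ and passes the
  discrimination arm (maximal discrimination).
- **PR stabilization**: the earliest 3-day window whose daily reward counts
  all lie within `tol` of the window mean, with `tol = max(1, 0.10 × mean)`
  for means ≥ 10 rewards and `tol = 1` below (the relative band would
  otherwise be stricter than one reward). The reported breakpoint is the
  window mean.

Two details of the stabilization rule are genuinely open in the protocols
this package models: whether the ±10% band anchors on the window mean, the
first day, or the median, and whether the reported breakpoint is the window
mean or the final day. We anchor on the mean (symmetric reading of "the
same number of rewards") and report the mean; `anchor="first"` and
`breakpoint="final"` are provided for comparison with rigs that resolved
the ambiguity differently. No upper cap on PR days is part of the
criterion; the simulator's protocol applies a 30-day safety cap and reports
non-stabilizing mice as missing rather than guessing a value.

## Virtual mouse

The generative model is deliberately minimal — three mechanisms, each tied
to one empirical signature, with no claim to neurobiological mechanism:

1. **Throughput.** While engaged, inter-poke intervals are exponential with
   rate `poke_rate_hz`: a fully engaged 60-min session is a Poisson stream
   of ≈ `3600 × poke_rate_hz` pokes.
2. **Learning.** Each poke picks the active well with probability
   `p_active(day) = floor + (ceiling − floor) · logistic((day − midpoint) /
   slope)`. The day counter accumulates across phases, so discrimination
   carries from FR1 into FR5 and PR.
3. **Persistence.** In PR sessions only, immediately after earning reward
   *k* the agent stays engaged with probability `exp(−r_{k+1} /
   persistence)`, where `r_{k+1}` is the next requirement. Disengagement is
   absorbing for the session; the agent then pokes at `disengaged_rate_hz`
   (default 0.01 Hz) with no well preference. Residual poking can still
   trickle in an occasional late reward — the chamber does not know the
   mouse has quit — which is physically faithful; analyses that need the
   disengagement point itself can set `disengaged_rate_hz = 0`.

Between-mouse variability: each parameter is drawn per mouse from its
genotype profile — lognormal for positive parameters (parameterized by
arithmetic mean and log-SD), logit-normal for probabilities. In the frozen
default profiles only `persistence` differs between genotypes, encoding a
motivation-specific deficit with fixed-ratio behavior left intact.

### Frozen default parameters

| parameter | units | mean | dispersion | rationale |
|---|---|---|---|---|
| `poke_rate_hz` | Hz | 0.076 | 0.17 (log-SD) | 0.076 × 3600 ≈ 274 pokes per engaged hour, the FR5 throughput anchor |
| `p_active_floor` | prob. | 0.50 | 0 | naive mice have no side preference |
| `p_active_ceiling` | prob. | 0.92 | 0.80 (logit-SD) | asymptotic discrimination; the low tail (< 0.75) produces the ~5% of mice that never meet the 3:1 criterion |
| `learning_midpoint_day` | days | 4.2 | 0.50 (log-SD) | centers acquisition near day 7.5 with SD ≈ 2.4 |
| `learning_slope_days` | days | 1.0 | 0.20 | few-day transition from naive to asymptotic |
| `persistence` (wild type) | pokes | 330 | 0.90 | mean stabilized breakpoint ≈ 9.8 |
| `persistence` (mutant) | pokes | 58 | 1.00 | ≈ 37% breakpoint reduction at d ≈ 1.7 |
| `disengaged_rate_hz` | Hz | 0.01 | 0 | sparse residual checking after quitting |
| `disengaged_p_active` | prob. | 0.50 | 0 | no preference once disengaged |

These values were fixed once by a coarse grid search against the study
conditions the simulator emulates — FR1 acquisition in ~7.5 ± 2.4 days with
~5% exclusions, ~273 total pokes per FR5 session, and a 37–46% mutant
breakpoint reduction with d ≈ 1.6–1.8 — and are not adjusted thereafter.
The absolute wild-type breakpoint is not pinned by any published number;
~9.8 rewards is a free choice consistent with the 60-minute clock (the
cumulative requirement through 12 rewards, 216 pokes, is about what a
0.076-Hz poker can deliver in an hour).

### What the generator does and does not emulate

It reproduces the *population-level* signatures above, plus their natural
couplings (e.g. slower pokers earn fewer rewards everywhere). It does not
model satiety or within-session rate decay, circadian or inter-day
carryover, body weight and food restriction, re-engagement after quitting,
or any neural mechanism. Passing tests therefore demonstrate that the
pipeline recovers known parameters from data *of this structure* — not that
real mice behave like the model.

### Randomness

One master seed per cohort; `numpy` `SeedSequence` children are spawned per
mouse and, within a mouse, per session, so results are reproducible and
enlarging a cohort never perturbs mice already simulated.

## Statistics

Group inference is Welch's unequal-variance t-test (two-sided, via
`scipy.stats.ttest_ind(equal_var=False)`); effect size is Cohen's d on the
pooled SD, uncorrected by default (a Hedges flag exists). Analytic power
for the two-sample t-test uses the noncentral t distribution with
noncentrality `d·√(n1·n2/(n1+n2))` and `n1+n2−2` df — the classical
pooled-variance formulation used by standard power calculators. The
asymmetry (Welch for inference, pooled for power) is deliberate and matches
field convention. The cohort report applies no multiple-testing correction
across its metric rows, mirroring how such panels are conventionally
reported; treat its p-values accordingly.

## Problem sizes

The test suite and the acceptance script run cohort-level checks at 20
replicate cohorts of 12 + 12 mice (calibration targets) and 1,000 cohorts
for the null false-positive rate, sizes at which the Monte-Carlo error of
each checked quantity is several times smaller than its tolerance band.
Single-parameter recovery checks use 1,500 sessions (binomial SEs ≈ 1%).

## Known limitations

- The stabilized breakpoint of a simulated mouse is a selected 3-day mean,
  so its day-to-day sampling noise is suppressed relative to single-session
  breakpoints; comparisons with rigs reporting final-day breakpoints should
  use `breakpoint="final"`.
- Welch's test on small groups of window-mean breakpoints is only
  approximately calibrated; the null-cohort check verifies the 5% level at
  n = 12 per group, not for much smaller groups.
- The event-log CSV carries the session config and end reason in the
  `well` column of the boundary rows (the format has no dedicated columns);
  third-party parsers should ignore those two cells if they only want
  pokes and rewards.
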