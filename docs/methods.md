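# Methods

## Scope and data model

`alarmsim` analyzes long-format numeric vital-sign time series — one row
per (patient, channel, time, value) — for a closed channel vocabulary: HR
(beats/min), RR (breaths/min), SPO2 (%), SBP/DBP/MAP (mmHg), TEMP (°C).
Monitoring devices of this class stream a continuously-updated 3 s moving
average of each numeric; the package treats the file values as that
displayed numeric and provides `moving_average` for re-smoothing raw
numerics when needed. The nominal cadence defaults to 1 sample/s and is
configurable per file; device numeric cadence is rarely documented, and all
rates are normalized by monitored time, so the cadence choice affects only
duration quantization (see below).

**Gaps.** Consecutive samples further apart than twice the nominal interval
are separated by a gap. Gaps split every computation into gap-free runs: a
moving-average window never spans a gap, a threshold-violation episode
never spans a gap, and every alarm timer effectively pauses. Monitored time
is one nominal interval per sample, which makes session duration and alarm
rates invariant under splitting a record at a gap. A cohort may hold
several sessions for one patient (e.g. a record split at a dropout);
patient counts deduplicate ids.

## Alarm simulation

An **episode** is a maximal run of consecutive samples violating a
one-sided limit. Conventions, each surfaced as a parameter so the
alternative can be run:

* *Boundary*: strict comparison (`value < low`, `value > high`); the
  threshold itself is the last acceptable value (`inclusive=True` gives the
  `≤`/`≥` variant).
* *One alarm per episode*: a persisting violation never re-annunciates.
  This matches counting alarms that "resolve by themselves" and keeps the
  grid semantics unambiguous.
* *No hysteresis*: a single in-limits sample ends the episode and resets
  the delay timer.
* *Censoring*: an episode still active at the record end or at a gap is
  counted, with its observed duration, and annunciates only if that
  observed duration already reached the delay — no unobserved persistence
  is assumed.

An annunciation delay `d` keeps exactly the episodes with duration ≥ `d`.
Episode durations are sample counts × nominal interval, so they are
quantized to the cadence: an excursion of true length `t` starting at a
random phase yields a measured duration within one interval of `t`. At 1 Hz
this shifts a duration-CDF readout at `T` seconds to roughly the true CDF
at `T − 0.5` s; at coarse cadences (≥ 10 s) excursions shorter than the
interval can be missed entirely, which is the physically correct behaviour
of a slow sampler.

**Rates.** `alarm_rate` is the pooled cohort-level rate: total annunciated
alarms ÷ total monitored patient-time on that channel, in
alarms/patient/day. Pooling (rather than averaging per-patient rates)
matches how a pooled database is summarized. `rate_grid` tabulates rates
over a threshold × delay grid, detecting episodes once per threshold and
filtering by duration per delay, so each cell equals the standalone
single-setting computation. Values are kept at full precision; rounding to
one decimal is presentation-only (a rounded total therefore need not equal
the sum of rounded components).

Structural behaviour: rates are always non-increasing in the delay. Rates
are monotone in the threshold *in the tail regime* where alarm limits
actually live; if a limit is moved into the bulk of the distribution,
raising it further can merge many short episodes into few long ones and
lower the episode count. The worked example shows this: a low-SpO₂ limit of
89 % sits above the 1st-percentile baseline, so chronically-low patients
produce fewer, longer episodes than at 87 %.

**Total burden.** A settings profile assigns each channel an optional high
and low limit (threshold + delay). The per-channel rate sums the two sides;
the total sums configured channels at full precision. Denominators are
channel-specific: a patient without a configured channel contributes
neither alarms nor monitored time to it (coverage of continual NIBP varies
across real databases). SBP and MAP are reported separately and also pooled
into a cNIBP roll-up row, the conventional single blood-pressure line for a
high-systolic + low-mean settings pair.

## Population statistics

* **Percentiles** are nearest-rank (value at index ⌈r·n/100⌉ of the sorted
  pool, no interpolation) — exactly reproducible across implementations.
  Samples pool with equal weight, so long-monitored patients contribute
  more, as in a measurement-level database.
* **Mean and CI**: the pool holds repeated measures on far fewer patients
  than measurements and the within-patient correlation is unknown, so the
  95 % CI is conservative: `mean ± t(0.975, df) · sd(pooled)/√n_patients`
  with `df = n_patients` (switchable to `n_patients − 1`). The convention
  is recorded in the profile metadata; the `√n_patients` standard-error
  denominator is this package's reading of that conservative convention.
* **Histograms** use integer-aligned bins (edges at multiples of the bin
  width) spanning the observed range, with heights
  count/(total · bin width), so the area is exactly 1.

Published distribution rows from three general-care-unit studies (the
continual cloud-hosted database, the intermittent Bleyer cohort and the
continual Tarassenko cohort) ship in `alarmsim.reference` as comparison
fixtures for `compare_profiles`.

## Synthetic cohort generator

The published record determines two observables — per-channel marginal
percentile tables and the excursion-duration quantiles — and the generator
pins exactly those, with minimal further assumptions:

* **Baselines.** A piecewise-linear quantile function (inverse CDF) is fit
  through the percentile anchors; per-patient baselines are drawn by
  inverse-transform sampling. Tails are flat by default (constant beyond
  the 1 % and 99 % anchors — conservative, since the tables end there);
  a linear-extrapolation tail rule is available. Baseline ranks are
  *stratified* across the cohort (patient *p* draws uniformly within
  [p/n, (p+1)/n]): the pooled marginal then matches the quantile curve to
  O(1/n) rather than the O(1/√n) of iid draws, which is what makes a
  500-patient cohort reproduce anchors to within ~1 unit. Stratification is
  switchable off (`stratify_baselines=False`) for strictly iid cohorts.
* **Fluctuation.** Stationary zero-mean AR(1) noise around the baseline
  with per-channel marginal sd (defaults: HR 1.5, RR 0.75, SPO2 0.5,
  SBP 2.5, MAP 2.0 units) and a 300 s correlation time. The sd defaults are
  deliberately small relative to inter-anchor spacing: the generator's
  contract is to reproduce the published marginals, and baseline+noise
  convolution widens the pooled distribution at steep quantile segments.
* **Excursions.** Poisson arrivals (default 0.2 events/h per configured
  stream — an artifact choice; the published record reports no excursion
  frequency), thinned so events never overlap or merge. Durations are
  log-normal with parameters solved in closed form from two quantile
  constraints, by default (30 s, 0.71) and (120 s, 0.95):
  `σ = (ln t₂ − ln t₁)/(z₂ − z₁)`, `μ = ln t₁ − z₁σ`. During an event the
  value is held a fixed depth beyond the stream's reference threshold
  (e.g. SpO₂ floor 80 against a limit of 85), so every excursion is
  detectable by construction. Default streams target the default alarm
  settings on each channel.
* **MAP anchors.** The published distribution tables carry no MAP row, but
  the default settings profile alarms on low MAP; the generator ships a
  clearly-labelled *synthetic* MAP anchor set chosen as a plausible
  general-care profile. It is a package choice, not published data.
* **Reproducibility.** One global seed drives a per-patient, per-channel
  counter-based substream (`SeedSequence(entropy=seed, spawn_key=(patient,
  channel))`), so cohorts are bit-identical for a given configuration
  regardless of generation order. SpO₂ is clipped to [1, 100] after
  synthesis. Optional Poisson gap injection deletes sample spans to emulate
  dropouts (off by default).

`excursion_study_config` is the measurement configuration for
duration-model recovery: a single HR channel with one low-excursion stream
against a 30 beats/min limit. The baseline floor (50) and small fluctuation
guarantee every detected episode is a generated excursion, isolating the
calibrated duration law; its 1.5 events/h arrival rate makes a 150-patient
× 24 h cohort yield ≈ 5000 episodes, the scale at which percentage-point
readouts of the duration CDF are stable.

**What the generator does not emulate:** coupling between channels,
circadian rhythm, disease trajectories, motion/sensor artifact structure,
or the absolute excursion frequencies of any real ward. Absolute projected
rates and total-burden figures on synthetic cohorts therefore characterize
the method, not any hospital; passing recovery tests shows the pipeline
measures back what the generator encodes, not that real alarm burdens are
predicted.

## Problem sizes and numerical choices

Default test and acceptance runs use desk-scale cohorts chosen for stable
statistics: 150 patients × 24 h at 1 Hz (≈ 13 M samples, ≈ 5000 episodes)
for duration recovery, 500 patients × 24 h at 0.1 Hz for marginal-mean
recovery, and 60-patient cohorts for burden comparability. Episode
detection is vectorized (run-length encoding on boolean masks); generation
is O(samples) via a single linear filter per channel. CSV round-trips use
shortest round-trip float repr on write and round-trip parsing on read, so
file cycles are bit-exact. Percentile ties break by sort order
(irrelevant for nearest-rank values); histogram top edges are extended by
one bin width when float round-off would drop the maximum.

## Known limitations

* One alarm per episode means very long violations are under-counted
  relative to monitors that re-alarm; the `inclusive` boundary and delay
  conventions cover the stated alternatives, but re-annunciation is out of
  scope.
* The patient-df CI is deliberately conservative; it is not an estimate of
  the true repeated-measures variance.
* Threshold-monotonicity of rate grids is a tail-regime property, not a
  theorem (episode merging; see above).
* Clinical actionability of suppressed or annunciated alarms is entirely
  out of scope: the package counts alarms, it does not judge them.
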