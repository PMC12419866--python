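# Methods

## The measurement problem

Secure messaging inside the EHR is asynchronous: a clinician can hold
several conversation threads open at once, interleaved with chart work.
`convoload` operationalizes that *conversational multitasking* as a daily
exposure, derives two audit-log workload outcomes, and estimates their
association with a linear mixed model. All timestamps are handled
timezone-naive in local time, and the unit of analysis is the
clinician-day: one clinician's activity within one local calendar day.

## Exposure: concurrency of active conversations

A thread is **active** from the clinician's first to last message activity
(send or read) in that thread within the day. Threads are clipped to
calendar days — a thread with activity at 23:50 and 00:10 contributes a
separate (here zero-length) interval to each day; there is no
cross-midnight stitching. A single-activity thread yields a zero-length
interval.

The day is tiled with half-open bins `[t, t + w)` aligned to midnight,
`w ∈ {1, 2, 5}` minutes (1 is the primary analysis). An interval is
counted in a bin when it covers any instant of the bin, with the interval
treated as half-open `[start, end)`: a thread ending exactly on a bin
boundary is not active in the bin that starts there. Zero-length intervals
are active in the single bin containing their timestamp — a read message
plausibly occupies attention for at least an instant, and dropping such
threads entirely would make single-message conversations invisible to the
exposure. These two conventions make the canonical three-thread example
(8:30–11:00, 8:40–10:30, 9:30–11:30) reproduce its piecewise-constant
trace exactly: 0 concurrent on 8:30–8:40, 2 on 8:40–9:30, 3 on 9:30–10:30,
2 on 10:30–11:00, 0 on 11:00–11:30.

Per bin, `n_active` is the number of active threads and the reported
**concurrency** is `n_active` when `n_active ≥ 2`, else 0 — a lone open
conversation is not multitasking. The day's exposure category comes from
`max n_active`: `NONE` (≤1), `TWO`, `THREE`, `FOUR_PLUS` (≥4).

Two derived covariates: **total messaging time** is the measure of the
union of active intervals (minutes with ≥1 active thread), not the sum
over threads; **percent concurrent time** divides minutes with ≥2 active
threads by that union (0 for a day with no messaging). The union reading
of "total messaging time" is a choice; the sum-over-threads alternative
would double-count overlapped minutes and can exceed the day length.

A note on bin-width orderings: coarsening can only merge activity when the
finer grid refines the coarser one. Since 1-minute bins tile both the 2-
and the 5-minute grids, `max n_active` at width 1 is ≤ its value at widths
2 and 5, and a day's category never downgrades from width 1 to a coarser
width. No such ordering exists *between* widths 2 and 5 (2 does not divide
5): a 2-minute bin straddling a 5-minute boundary can merge threads from
both sides and exceed the width-5 maximum. The property tests assert the
refinement orderings only.

## Outcomes from the audit log

**EHR time** sums gaps between successive audit-log actions, dropping gaps
longer than the inactivity threshold (default 5 minutes; the comparison is
inclusive, so a gap of exactly 5 minutes counts as active). Fewer than two
events give 0; the trailing event contributes no imputed duration; events
with identical timestamps contribute zero-length gaps, so row order among
ties is irrelevant.

**Patient switches** counts pairs of consecutive *patient-attached* events
with different patient ids at most the threshold apart. Events without a
patient id are skipped when forming pairs and do not reset the clock: the
5-minute rule applies to the time between the two patient-attached events
themselves. This is the simplest internally consistent reading; an
alternative (resetting at any intervening event) would make the count
depend on patient-less housekeeping actions.

**Patient load** is the number of distinct non-missing patient ids in the
day — a pragmatic operationalization chosen here; census-based definitions
would need data the audit log does not carry.

## Cohort rules

A candidate clinician-day is any day with messaging or audit activity. It
is analyzable when all of the following hold, checked in a fixed order so
each excluded day carries exactly one reason
(`no_note → no_order → no_message → no_login → night_shift →
missing_demographics`):

1. ≥1 `note_sign` action; 2. ≥1 `order` action; 3. ≥1 message activity;
4. ≥1 login event (without one, neither shift nor service can be
   classified — such days are excluded under their own reason);
5. not a night shift — first login strictly before 05:00 or strictly
   after 17:00; logins at exactly 05:00 or 17:00 count as day shifts;
6. age and sex present in the roster (clinicians absent from the roster
   count as missing demographics, with a logged warning).

The daily **service** is the modal login context, ties broken by the
context that appeared first that day. In real Epic extracts the mapping of
action codes to `note_sign`/`order` is site-specific; the `action_type`
vocabulary here is the pluggable abstraction for that lookup.

An exclusion report (counts per reason, included, total) is emitted with
every build; conservation (`Σ reasons + included = candidates`) is

asserted in the test suite.

## The mixed model

For each outcome (EHR minutes; switch count, treated as Gaussian at the
daily scale where it is large and roughly symmetric):

`y = Xβ + Z_c b_c + Z_s b_s + ε`, with `b_c ~ N(0, σ_c² I)` over
clinicians, `b_s ~ N(0, σ_s² I)` over services, independent residuals.
The random effects are **crossed**, not nested — clinicians work across
services. Fixed effects: exposure category (reference `NONE`), percent
concurrent time, message volume, patient load, role (reference
`attending`), age in years untransformed, sex (reference `female`).

Estimation is REML. The default backend profiles `β` and `σ²` out of the
restricted likelihood and minimizes over the two variance ratios
`γ_i = σ_i²/σ²` (on the log scale, Nelder-Mead from two starts), doing all
per-iteration algebra in the K-dimensional random-effect space via the
Woodbury identity (`K` = clinicians + services). A 5000-row cohort with
~260 random-effect levels fits in ~0.1–0.4 s, which is what makes
200-replicate simulation studies routine. The identical model is available
through `statsmodels MixedLM` (`backend="statsmodels"`); the suite checks
both backends against each other and against `lme4` on a fixture, where
agreement is to ~4 significant figures, and additionally asserts the
profiled fitter never returns a worse restricted likelihood than the
alternative optimizer.

Inference: Wald 95% CIs (`β̂ ± 1.96·SE`) and normal p-values, conditional
on the estimated variance components; no multiple-testing adjustment. The
exposure × role interaction is tested by a likelihood-ratio test on ML
refits (χ² with one df per interaction column); when it is of interest,
role-stratified fits rerun the model per role with both random intercepts
retained. Degenerate cases are reported, not errored: a variance component
estimated at ~0 is returned as such; a single-service stratum drops the
service component with a warning and reports its variance as 0; a constant
outcome returns zero slopes with a zero-residual-variance warning. Missing
exposure levels or rank-deficient designs raise errors naming the term.

The sensitivity runner rebuilds the cohort and refits at bin widths 1, 2,
and 5; width 1 is bit-identical to the primary analysis.

## Synthetic generator

The generator emulates the three extracts with known ground truth.

*Roster*: roles drawn 54/27/19% attending/APP/trainee, ages ~N(42/40/30,
6) by role, 56% female, a configurable fraction (default 2%) with age and
sex absent (encoded as empty, never imputed).

*Messaging*: thread count per day ~ Poisson(8); thread durations
log-normal with median ~40 min (the marginal duration law is a modeling
choice — no empirical distribution was available to copy); each thread
carries its first and last activity plus ~Poisson(2.5) interior ones,
yielding a median daily volume near 37 messages. With probability
`overlap_intensity` (default 0.5) a new thread starts inside an open one,
forcing overlap; otherwise it starts after all open threads end, with an
inter-episode gap of 5 + Exp(20) minutes. The 5-minute floor reflects that
distinct conversation episodes are minutes apart, and has the consequence
that sequentially placed threads never merge spuriously at any supported
bin width; residual category shifts at coarser widths can still arise from
near-boundary geometry among overlapped threads. `overlap_intensity=0`
therefore guarantees a `NONE` day. Threads never span midnight by default;
a flag enables spill-over to exercise the day-clipping rule.

*Audit log and planted effects*: effects are planted on the
**derived-metric scale**. For each day the realized exposure category and
message volume are measured from the generated messaging, patient load is
drawn (1 + Poisson(6)), and target outcomes are drawn from

`target = intercept + β[category]·role_scale + β_vol·volume +
β_load·load + b_clinician + b_service + ε`,

with defaults calibrated to the descriptive scale of a large inpatient
cohort: intercepts 200 min / 60 switches; exposure effects 20.3/38.0/54.8
min and 14.5/26.7/41.6 switches for TWO/THREE/FOUR_PLUS; volume slopes
0.37/0.28; load slopes 7.0/4.0; SDs σ_resid = 60/40, σ_clinician = 30,
σ_service = 15. The audit stream is then *constructed* to hit the targets
exactly: a chain of events whose gaps (≤4 min each) sum to the EHR-time
budget; patient ids sequenced to realize exactly the target switch count;
patients beyond the switch budget attached to events isolated by
above-threshold gaps (adding load but neither time nor switches); a login
(with the day's service context, occasionally plus a minority context),
a note-sign, an order, and a patient-less interloper event included. A
time budget that cannot fit the remaining day is clipped with a logged
warning (night-shift days, which start late, are the usual case — and are
excluded by the cohort rules anyway). With all SDs at zero the derived
outcomes round-trip to the planted linear predictor within 1 minute and
0 switches, which the acceptance tests assert.

`simulate_cohort_table` draws the analyzable clinician-day table directly
from the same planted model (category frequencies 45/25/15/15%, volume
log-normal scaled up with category), skipping event construction. It is
the engine for the Monte-Carlo recovery study — 200 replicates of 5000
clinician-days (250 clinicians × 20 days, 12 services) in which the REML
estimates of the planted exposure effects must show <5% relative bias and
~95% CI coverage. Event-level fidelity is established separately by the
round-trip tests, so the two routes together cover what a 200-replicate
event-level simulation would, at a fraction of the cost.

What the generator does *not* emulate: message content and recipients,
real hospital census dynamics, behavioral feedback between messaging and
chart work (effects are injected, not emergent), within-day correlation of
audit actions beyond the constructed gaps, and skew/overdispersion of the
switch outcome beyond what the linear model implies. Passing tests
demonstrate that the measurement chain and estimator are correct under
these planted conditions — not that the linear mixed model is the right
substantive model for any particular health system's data.

## Numerical choices and edge cases

- Gap comparisons are inclusive at the threshold ("exceeding" excludes).
- Negative gaps after the defensive stable sort (duplicate timestamps out
  of order) are treated as 0.
- Bin assignment uses integer second arithmetic (`start // w`,
  `ceil(end / w)`); timestamps are second-resolution so binning decisions
  are exercised nontrivially at every supported width.
- Variance ratios are optimized on the log scale, unbounded below, so a
  component can go to ~0 smoothly; two starting points guard against the
  flat region near zero.
- Empty interval sets, empty days, and empty cohorts are valid (empty
  trace, zero summaries) or explicit errors (descriptives on an empty
  cohort), never silent misbehavior.

## Known limitations

- Switch counts are modeled as Gaussian, matching the analysis design it
  reproduces; a count model (e.g. negative binomial GLMM) would be the
  natural extension for low-volume settings.
- Wald CIs and normal p-values ignore variance-component uncertainty;
  profile or bootstrap intervals would be more conservative in small
  cohorts.
- The night-shift rule keys on the first login only; split shifts and
  cross-midnight shifts are classified crudely, as in the original design.
- `pct_concurrent_time` and the exposure category are deterministically
  related within a day (both derive from the same trace), so their joint
  inclusion relies on across-day variation; with very small cohorts this
  can make the design nearly collinear.
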