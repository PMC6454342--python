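# Methods

`screenuse` quantifies smartphone use from passively logged screen events
and asks two reliability questions about the resulting daily parameters:
how short a recording block still represents a person's typical two-month
use (*fundamental time unit*), and how far apart two recording periods can
be before they no longer measure the same behavioural regime (*independent
cycle*). Because event-level smartphone datasets are rarely shareable, the
package ships a calibrated synthetic cohort generator so that every stage —
episode segmentation, the seven parameters, and both stability analyses —
is testable end to end.

## Episodes

A **use episode** is the half-open interval from a `screen_on` event to the
next `screen_off`; the waking gaps between uses are **nonuse episodes**.
Each local calendar day (midnight to midnight, user's timezone from the
configuration) is one analysis unit whose episodes strictly alternate
use/nonuse and tile the full 86 400 s, including the midnight-bounded gaps
before the first and after the last use. Use intervals crossing midnight
are split at the boundary so daily totals stay bounded by one day.

Event streams from real devices are imperfect; the resolution rules are
deterministic and QC-counted, never silent:

* a second `screen_on` before any `screen_off` supersedes the first
  (duplicate wake events behave this way on handsets);
* an orphan `screen_off` and a zero-length interval are dropped;
* uses touching exactly (off == next on) merge into one episode;
* a trailing unclosed `screen_on` is dropped.

A use episode is **proactive** when no notification arrived in the
half-open window `[screen_on − 60 s, screen_on)`, **reactive** otherwise.
A notification exactly at screen-on does not count: the screen is already
turning on. Enlarging the window can only turn proactive labels reactive,
never the reverse; a property test asserts this monotonicity.

Each user's first and last calendar day is excluded by default as
incomplete (partial recording on installation/removal days).

### Sleep

Sleep must not count as nonuse time, but event logs contain no sleep
marker. The default policy, `longest_overnight_gap(min_hours=4,
night 21:00–11:00)`, flags — per day — the single longest nonuse gap that
overlaps the night window and lasts at least 4 h. Because days are cut at
midnight, the short pre-midnight tail of a night gap on the *previous* day
is not flagged under this policy; the alternative `fixed_window` policy
(which splits episodes at the window edges and flags exactly the overlap)
removes that tail deterministically, and `none` disables exclusion. Sleep
detection from screen gaps is a heuristic, not actigraphy; this is the
biggest modelling assumption in the pipeline and it is fully
config-switchable.

Flagged time contributes to no parameter. For the reciprocity statistics
the flagged gaps are removed from the sequence and, by default, their
neighbours become adjacent (`bridge_sleep_gaps=True`); the alternative
breaks the day into segments at each removed gap so no successive
difference or lookahead straddles sleep.

## The seven daily parameters

With use episodes `Y` and nonuse episodes `X` of one day (sleep removed):

* `F` — number of use episodes; `D` — summed use seconds;
* `PF`, `PD` — the same restricted to proactive episodes;
* `RMSSD` — with the alternating durations `A_1..A_n` in temporal order,
  `sqrt( Σ_{i<n} (A_{i+1} − A_i)² / (n−1) )`; undefined for `n < 2`;
* `SI` (Similarity Index) — mean `|X_i − Y_j|` over each nonuse episode
  and its `k = 3` following uses; a nonuse episode with fewer than 3
  following uses in its day is skipped entirely;
* `CI` (Control Index) — mean `|X_i − (Y_i + Y_{i+1} + Y_{i+2})|` over the
  same eligible gaps.

Low RMSSD/SI mean an even use/nonuse rhythm; low CI means pauses are
commensurate with the use they precede — an index of use-control ability.
Two denominators are defensible for SI (pooled over all 3k differences, or
a mean of per-gap means); they coincide when every gap is eligible. The
pooled form is the default and the choice is a config switch
(`si_pooled_denominator`). All three statistics are undefined — never
zero — on degenerate days, since zero would fake perfect reciprocity;
period means skip undefined days and record per-field contributing-day
counts.

All three are checked against independent brute-force loop implementations
on 1 000 random alternating sequences (≤ 1e-9 relative) and satisfy scale
equivariance (×c scales all three by c) and RMSSD translation invariance.

## Stability analyses

Both analyses correlate *across users* (Pearson r; two-sided p from the t
transform; cells with fewer than 3 users or zero variance are reported
undefined, never 0 or 1).

* **Fundamental time unit**: for units of 1, 2 and 4 weeks, the
  grid-aligned blocks (weeks 1..8; 1–2, 3–4, …; 1–4, 5–8) of per-user
  block means are each correlated with the per-user 8-week mean. The block
  is part of the whole — this part–whole overlap is intentional and
  matches how such reliability curves are usually read. A cell is flagged
  "high" at r ≥ 0.75 (configurable).
* **Independent cycle**: blocks of 1 or 2 weeks at *sliding* weekly
  offsets are paired without overlap; the gap between them is the time
  interval TI. All pair correlations at a TI are averaged into `mean_r`.
  For 1-week units in an 8-week record the pair counts at TI = 0..6 are
  7, 6, 5, 4, 3, 2, 1; for 2-week units at TI = 0..4 they are 5..1.

p-values are reported unadjusted; no multiple-testing correction is
applied (a deliberate limitation, matching standard practice for these
descriptive reliability curves). The exploratory analysis additionally
correlates each user's 2-month parameter means with the SPAI-5
questionnaire total (5 items, 1–4 Likert, totals 5–20) and emits the 7×7
parameter intercorrelation matrix.

## The synthetic cohort generator

The generator emulates a cohort of heavy adult smartphone users tracked
for 8 weeks. Defaults (the study conditions; all configurable):

| knob | default | why |
|---|---|---|
| users × weeks | 33 × 8 | the target study design |
| episode rate | lognormal, mean 57.29/day, SD 22.96 between users | observed cohort F |
| mean episode duration | lognormal across users, mean 360.7 s (CV 0.4) | makes mean daily D = 5.74 h |
| within-day durations | lognormal, σ = 1.0 | heavy right skew of episode lengths |
| proactive probability | Beta, mean 0.40, SD 0.15 | proactive share of frequency |
| proactive duration factor | 0.575 | proactive episodes are shorter: 0.40 × 0.575 = 23% of duration |
| sleep window | ≈ 23:30 → 07:30, per-user normal (SD 0.5 h), fixed per user | nightly no-use period |
| weekend multiplier | lognormal, mean 1.15 | weekly cycle; profile normalized to mean 1 |
| drift | geometric random walk on the rate, step SD 0.10/week, mean-corrected | slow regime change; makes correlations decay with TI |
| SPAI-5 map | affine from the latent to mean 12.55, SD 2.41, rounded, clipped to [5, 20] | questionnaire total distribution |

Episode counts are Poisson; gaps partition the remaining waking time via a
flat Dirichlet. The addiction latent follows a Gaussian-copula
construction: it correlates 0.4 (configurable) with the within-cohort
standardized log of each user's expected proactive duration
(rate × duration × proactive fraction × factor), plus independent normal
noise. Reactive episodes receive exactly one notification placed uniformly
inside the 60 s pre-onset window and provably outside every proactive
episode's window (when onsets crowd within 60 s and no legal slot exists,
the episode is flipped to proactive — measured flip rate ≈ 0.03% of
episodes) — so the downstream classifier's labels equal the generator's
labels for 100% of episodes, and the label pathway is exactly testable.

Numerical/realism notes:

* Durations are resampled (≤ 100 times) when a day's draws exceed 90% of
  the waking window, then scaled as a last resort with a warning. This
  waking-time cap truncates the heaviest users' days, so measured cohort
  mean D typically reads ~2–7% below the idealized rate × duration product
  — real phones are subject to the same cap.
* The weekly profile and drift walk are mean-normalized, so cohort
  expectations factorize: E[F] = 57.29, E[D] = 5.74 h, PF/F = 40%,
  PD/D = 23% by construction (`expected_daily_summary`).
* The generator emits exactly `7 × n_weeks` calendar days; downstream
  first/last-day exclusion then leaves `7·n_weeks − 2` analysis days, so
  the last analysis week is partial. Week indices are cohort-aligned from
  the first included day.

What the generator does **not** emulate: within-day circadian structure
beyond the sleep window, app-level content, missing data/compliance gaps,
and the very large dispersion of proactive duration seen in some real
cohorts (between-user PD dispersion is configurable but defaults to a
moderate value). Passing tests therefore show that the *pipeline and
statistics* behave correctly under the assumed generative structure, not
that real populations satisfy that structure.

## Problem sizes and margins

The Monte-Carlo suites use 20 replicate cohorts of 100 users × 8 weeks for
the stability-recovery checks and one 500-user cohort for the
questionnaire-correlation check; these sizes give replicate standard
errors of mean_r around 0.005–0.01, and the monotonicity margins (0.02 on
replicate-averaged correlations) were fixed in advance from those errors.
Zero-drift cohorts must put every 2-week-unit correlation above 0.75;
under drift (step SD 0.2/week) the TI profile must be non-increasing
within the margin and clearly lower at TI = 4 than without drift. The
copula targeting 0.4 must surface as r(PD, SPAI-5) ∈ [0.25, 0.55] at
n = 500 — the linear-scale correlation is attenuated (~0.30–0.38) relative
to the log-scale construction because proactive duration is right-skewed.

## Known limitations

* Sleep detection is heuristic; under the default policy a pre-midnight
  sleep tail can leak into nonuse time (see above).
* A use episode split at midnight counts once in each adjacent day's F.
* Pearson r across 33 users is noisy (SE ≈ 0.15 near r = 0.4); the
  default-cohort addiction correlation varies accordingly between seeds.
* Undefined-day handling (drop with counts) differs from imputation; with
  the default generator no day is degenerate, so this path is exercised
  only by constructed fixtures.
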