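# Methods

## Scope and shape

`econsult` is a single-period, staff-time costing model of a web-based
consultation service in general practice, with usage analytics and a
synthetic event-log generator around it. It deliberately excludes
discounting, multi-year horizons and QALY/ICER machinery: the decision
it supports — does the time saved cover the licence charge, and at what
usage? — is a same-year staffing question. Unit costs (GBP per hour of
GP and administrator time) are configuration inputs, not derived here.

## Time model

Seven outcome categories partition submissions. Admin minutes per
category are *receive* + *close-off*; the close-off is the longer
with-contact variant (3 min vs 1.5) for the five categories whose
outcome must be communicated to the patient (fit note, prescription,
other appointment, phone back, face-to-face appointment) and the short
variant for details changes and no-action follow-ups. The source tables
do not state this assignment; it is the unique assignment under which
the per-category admin column follows from the elementary timings, and
is flagged as an inference here and in `timings.CONTACT_CLOSE_OFF`.

GP minutes are a note check (a 50/50 mixture of minimal 2.5-min and
detailed 5-min review by default, via `NoteUseModel`) plus the
category's increment, except that details changes (0.5 min) and fit
notes (4 min) are flat tasks. Phone-back and appointment outcomes carry
their follow-up contact (5 / 10 min) as a separate component so reports
can print the "3.75 + 5" decomposition.

Expected minutes are the mix-weighted sums, kept at full precision
(5.67 / 5.9125 under defaults). Rounding — half away from zero, which
matches every printed reference cell — happens only at presentation.
Carrying rounded expected times into the money table reproduces none of
its cells exactly; this is why `ExpectedResource` exposes both.

## Cost model

A saved conventional contact is one 3-minute booking call plus one
10-minute face-to-face appointment. Telephone consultations are not part
of the comparator: including them cannot reproduce the reference money
table. Hourly rates are divided by 60 at full precision (pre-rounded
per-minute rates also fail to reproduce the table). Break-even is
`charge / total_saving` when the saving is positive and an explicit
undefined value otherwise — never infinity, so reports print
"no breakeven" rather than propagating non-finite numbers.

The replacement share `s` is an input everywhere, not hard-coded: the
observed mix implies 0.73 raw, 0.67 after the 8% induced-demand
discount, and the published sweep runs 0.74 down to 0.60; all three
appear only as defaults or example arguments.

The sensitivity sweep scales administrative timings by (1 ± x) in two
variants — submission-side tasks only (receive, close-off), or all admin
tasks including the comparator's booking call — because the question
"admin timings are uncertain" is ambiguous between the two. Both are
reported; under defaults a ±20% swing moves the total saving by ≤ £0.34
against a GP component of ~£9.4/h·equivalents, supporting the
qualitative claim that admin-timing uncertainty is second-order.

## Scenario engine

`appointments_saved` sums mix probabilities over the saved-category set.
Phone-back is counted as saved even though it consumes GP phone time:
the saving is of the face-to-face slot, and the phone minutes are
already charged on the processing side — this is required for the raw
share to come out at 0.73 and for the money and scenario tables to be
jointly consistent. Scenario mixes are data (`data/scenarios.yaml`), not
code; each scenario declares its admin and recall shares redundantly and
the constructor validates them against the mix, so a transcription error
in a user scenario file fails loudly. Break-even is evaluated at the
£0.63 default charge and at any user-supplied alternative (£1.00 appears
in some published material for the same model; neither is asserted as
canonical).

## Usage analytics

All analytics are pure functions of the event log: re-running on the
same CSV gives identical output (the permutation test is seeded).
Demographics may be unknown — shares are computed over known values with
unknown counts reported alongside, never silently included in
denominators. The deprivation association is Spearman's rank correlation
of practice submission rates against SIMD quintile shares with a seeded
permutation p-value (999 permutations by default): the original claim in
this literature is visual ("no discernible relationship"), and the
statistic quantifies the same comparison; with fewer than three
practices it refuses, and constant inputs are flagged degenerate with
rho reported as 0 by convention. Survey proportions use Wilson 95%
intervals rather than Wald because the denominators are small and the
proportions near 1.

## Synthetic generator

The generator emulates the structure of a pilot panel: ~11 practices of
3–12k patients over a 5-month window (17 April–17 August); daily website
visits Poisson with mean proportional to the adult list (0.46 per 1000
adults/day), a mean-preserving linear upward trend (growth parameter
0.8) emulating adoption growth, and practice-level lognormal rate
heterogeneity (σ = 0.5, demeaned in log space); independent Bernoulli
conversion of visits to submissions (0.30); broad-class mix
32/27/24/17% (specific condition / administrative / new advice /
existing advice); submission demographics drawn from the practice roster
reweighted by usage multipliers — female odds 1.996 and a 1.641
multiplier on the 18–44 bands, calibrated once by
`scripts/calibrate_generator.py` so the pooled panel shares hit the 67%
female / 64% young-adult targets (a single-roster analytic back-solve
lands ~1 pp high on the young-adult share because the panel is
heterogeneous and includes a forced young-skewed outlier practice); a
zero SIMD slope by default (the null deprivation gradient), exposed as a
log-linear `simd_effect` for power studies; and a voluntary survey with
6.5% response, 91.4% satisfaction, 91.5% recommendation probabilities.
Rosters include one forced young-skewed (65+ share 2.3% of roll) and one
old-skewed (28.1%) practice. With the default rate, pooled usage is
~0.05 submissions per patient per year.

Chosen defaults not fixed by the study conditions: the 5% urgent-divert
probability, the 80% unique-visit flag probability, the Dirichlet
concentration (120) of roster age profiles, and the list-size range —
picked once as plausible for Scottish general practice and not
revisited. Timestamps are dates only; no within-week or diurnal pattern
is modelled.

What the generator does *not* emulate: marketing-driven behaviour
changes, practice drop-out mid-window, seasonal illness patterns, or any
mechanism behind the demographic skews. Passing round-trip tests
therefore shows that the analytics correctly measure logs with this
statistical structure — not that real pilot figures are reproducible
(the underlying raw logs were never released, so they are not).

## Determinism and numerics

Every stochastic component hangs off one integer seed through
`numpy.random.SeedSequence` with distinct stream keys for rosters, rate
multipliers, events and survey, so rosters are identical across
configurations that only change event-side parameters. Category-mix
normalisation is checked to 1e-9; savings additivity and the
break-even·saving = charge identity hold to 1e-9 and are tested; the
hypothesis monotonicity test ignores share differences below 1e-9,
the float resolution of the money scale.

## Test problem sizes

Round-trip recovery tests run the generator at a raised visit rate
(2 per 1000 adults/day) so a panel yields ≥5000 submissions, and pool
demographic shares over four panel draws, since panel-to-panel roster
variation — not multinomial sampling — dominates the variance of pooled
shares at that n; conversion recovery uses a single panel against exact
binomial bounds. The null-association check runs 50 replicates at 499
permutations. These sizes keep the full suite under half a minute while
leaving the checked tolerances (±2 pp on shares) comfortably above the
estimators' standard errors.

## Known limitations

- The with-contact close-off assignment and the category-level GP time
  composition are inferred from arithmetic consistency with the
  reference tables, not independently elicited.
- The comparator costs every avoided contact identically; in practice
  some submissions replace telephone consultations or nurse time.
- Induced demand enters as a single multiplicative discount on the
  replacement share; no behavioural model.
- The analytics treat the unique-visit flag as given; no 24-hour
  deduplication is attempted.
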