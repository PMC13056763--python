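# Methods

This note documents the statistical conventions of the evaluation chain
and the model behind the synthetic-cohort generator: what is assumed,
what each tunable parameter means, and what passing tests do and do not
establish about real data.

## Windowing and the reference standard

A participant's 32-h void stream is split into two 24-h collection
windows anchored at the morning and afternoon assessment times (8 h
apart by default), so the windows share the middle 16 h of voids. Window
membership is **half-open**, `(t − 24 h, t]`: a void produced at the
assessment moment belongs to the period it concludes, and a void at
exactly `t − 24 h` is excluded. The field protocol never forces a void
at a window boundary, so the convention only matters for synthetic edge
cases, but it is applied consistently everywhere. A window anchored
earlier than 24 h after the first recorded void is flagged `partial`
rather than rejected.

The reference quantity is the volume-weighted mean USG of the window,
`sum(USG_i * V_i) / sum(V_i)`, with urine mass read as volume at
1 g ≡ 1 mL. Floating-point round-off is clamped so the result never
escapes `[min USG_i, max USG_i]`. Reference labels compare the USG
**after rounding to 3 decimals** (the instrument's recording precision,
half away from zero), which removes float-representation ambiguity at
the cut-offs: low iff USG ≤ 1.012 under the low cut-off, high iff
USG ≥ 1.020 under the high one.

## Scoring conventions

All four item thresholds are inclusive on the low-concentration side
(≥ 2697/3697 mL, ≥ 7 voids, ≥ 250 mL, colour ≤ 2), as are the companion
predicates (thirst ≤ 40% of the 175-mm VAS, void duration ≥ 16 s,
body-mass decrease ≥ 1% from the day-1/day-3 average baseline; the
body-mass comparison carries a 1e-9 tolerance so an exact 1% decrease
computed in floats still flags). The thirst percentage uses the full
175-mm line as denominator; the 125-mm "extremely" anchor is recorded
in the schema but plays no computational role. Records missing any of
the four markers are excluded and reported, never imputed: the
instrument is defined only on complete records.

Under the low cut-off the positive (disease-analogue) class is
high-concentration/suboptimal intake, and that is the default
orientation everywhere. The development study's high-cut-off tables can
be read with either class as positive — its printed count margins imply
the majority class while its sensitivity prose implies the
underhydrated class — so `contingency`/`evaluate_model` expose the
positive class as an argument instead of hard-coding one reading.

## Diagnostic statistics

- **Rates** are reported as percentages rounded to 1 decimal, halves
  away from zero (21.875 → 21.9, matching how the development study
  printed its tables); raw fractions are kept alongside. A rate with a
  zero denominator is an explicit `None` sentinel, not an exception, so
  sparse per-item tables remain printable.
- **AUC** uses the rank (Mann–Whitney) formulation with mid-ranks on
  ties — the unique tie-consistent empirical AUC, identical to
  trapezoidal integration of the ROC curve and to exhaustive
  concordant-pair counting (both asserted to 1e-12 in tests). For the
  graded 0–4 model score this is the natural choice; whether the
  development study computed its AUCs from the integer score or from
  logistic predicted probabilities is not stated there, and this
  package always uses the score. Bands: excellent ≥ 0.90, good
  0.80–0.89, fair 0.70–0.79.
- **Effect sizes**: rank-biserial r = (W⁺ − W⁻)/(W⁺ + W⁻) over nonzero
  paired differences with mid-ranks on tied magnitudes (all-zero input
  → undefined sentinel); Cramér's V = sqrt(χ²/[n·(k−1)]) with Pearson's
  χ² **without** continuity correction (the defining formula has no
  correction term; the χ² *test* exposes Yates correction as an option);
  Spearman correlation as Pearson on mid-ranks.
- **Tests** are two-sided; the rank tests use the normal approximation
  with tie correction, Fisher's exact test enumerates 2×2 tables
  exactly.

## Stepwise selection

Forward–backward stepping on Wald p-values: each forward step admits
the candidate with the smallest p ≤ 0.10 (refitting the current model
plus one candidate at a time, covariates always adjusted for), each
backward step removes any retained term with p > 0.05; ties break by
declared column order, and a visited-model set guarantees termination.
Wald tests were chosen because the instrument's development procedure
reported odds ratios with confidence intervals; under perfect or
quasi-perfect separation (|β| > 25 or a separation warning from the
optimizer) the Wald statistic collapses, so the step substitutes a
likelihood-ratio test against the nested model and flags the fit.
Categorical covariates are reference-coded against their most frequent
level; constant columns never enter. Covariates are dropped from the
final model when they fail the retention threshold, mirroring a
development procedure in which no covariate proved significant. The
"practical relevance" judgment that a research team applies on top of
the statistical rule is not an algorithm; a `forced_include` list
stands in for it. Maximum-likelihood fitting is delegated to
statsmodels (Newton IRLS, tolerance 1e-8, ≤ 100 iterations).

For null-calibration runs the entry and stay thresholds are set equal
(0.10): with stay < entry a candidate that enters on p ≤ 0.10 is
immediately re-tested at 0.05, so the steady-state per-candidate
retention tracks the *stay* threshold; with equal thresholds it tracks
the entry rate, which is the property worth checking.

## The synthetic-cohort generator

The generator is a statistical emulator of a field validation study —
no renal physiology (osmolar clearance, vasopressin dynamics) is
modelled. One latent **fluid-balance adequacy** factor `a` per
participant (lognormal; median ≈ 1.16 relative to the sex-specific
reference intake of 2697/3697 mL) drives everything:

- **Latent USG**: `USG = 1.0125 + slope·(a − 1) + N(0, usg_noise_sd)`,
  clamped to [1.000, 1.040]. The anchor 1.0125 is the continuous
  boundary between the ≤ 1.012 and ≥ 1.013 reference classes, and the
  slope is ≤ 0 (default −0.008), so `a = 1` sits exactly on the
  low/high boundary and USG decreases with adequacy. Setting the slope
  to 0 severs markers from USG entirely.
- **Per-marker factor copies**: each marker taps its own
  `m_k = a · exp(N(0, marker_dispersion_sd))` (default sd 0.2). This is
  deliberate: intake is only one input to fluid balance while
  frequency, volume and colour reflect renal output, so each marker
  carries signal about USG the others do not fully contain — without
  this, the four items are conditionally redundant and no selection
  procedure could retain all four.
- **Calibrated marker maps**, each monotone in its `m_k` with the model
  cut-off at exactly `m_k = 1`: intake = `m · need(sex)`; 24-h void
  count = `floor(7 · m^0.8)` (floor of 7 at m = 1); spot volume =
  `250 · m^γ` mL with γ per session chosen so the median lands at the
  configured 450 mL (morning) / 330 mL (afternoon); colour from a fixed
  7-level breakpoint table over USG whose level-2/3 edge is 1.0125.
  Because of this joint calibration, a zero-noise cohort is classified
  **perfectly** by the 4-item rule — by construction, which is exactly
  what makes it a useful anchor for testing the chain.
- **Void streams**: 32 h from ~08:00 day 1, no voids in the sleep block
  (23:00–06:00), a forced overnight-accumulated first-morning void
  (~06:00–06:30) that doubles as the morning spot sample, and the last
  afternoon void as the afternoon spot. Per-void USG = latent USG +
  N(0, usg_noise_sd); 24-h urine volume targets
  `urine_output_fraction` (0.5) of daily intake.
- **Reporting noise** (`SelfReportNoise`): lognormal diary noise per
  period (cv 0.12), additive tally noise on the void count (sd 0.9),
  lognormal spot-volume noise (cv 0.18), ±1-level colour misreadings
  with probability `color_noise` (0.15), and a lognormal **morning
  drift** (sd 0.35) applied to the morning spot's volume and colour
  factors — the overnight sample reflects overnight state rather than
  the 24-h pool. This drift is the mechanism behind the
  afternoon-better-than-morning accuracy ordering.
- **Sessions**: thirst VAS and void duration are generated as candidate
  markers (duration = spot volume / 22 mL·s⁻¹ with noise — hence
  deliberately collinear with the volume item and excluded from the
  default distractor set); body mass and demographic covariates are
  pure noise with realistic marginals.

Default marginals (n = 1000): median 24-h urine volume ≈ 2.1–2.3 L,
void count 7, fluid intake ≈ 4.0–4.2 L, 24-h USG ≈ 1.011. One
descriptive quantity deliberately deviates from the emulated cohort:
the afternoon spot-volume median is ~330 mL rather than 250 mL, because
250 mL is the item cut-off itself and a median sitting exactly on the
cut-off would contradict the generator's cut-off ↔ `a = 1` calibration.
The two overlapping windows share one latent USG per participant;
between-window disagreement arises only from per-void noise in the
weighted means.

Presets: `zero_noise()` (all dispersion and reporting noise off —
perfect classification anchor), `uncoupled()` (slope 0 — chance-level
anchor), `strong_coupling()` (slope −0.012, usg noise 0.0015,
dispersion 0.25, tightened reporting noise — the marker-recovery
condition for selection).

**What passing tests do not show.** The generator reproduces marginal
medians and the qualitative coupling structure, not the joint
distribution of a real cohort: real markers are coupled through
behaviour and physiology (drinking in response to thirst, timing of
intake vs collection), inter-marker correlation here arises only
through the shared latent factor, and day-to-day within-person
variation is not modelled. Consequently the published AUCs
(0.72/0.85/0.81/0.86), the spot-vs-24-h accuracy percentages and the
development study's regression coefficients are **not** reproduction
targets at desk scale — they depend on the undeposited human dataset.
The chain reproduces their *arithmetic* (every printed
sensitivity/specificity from its printed counts) and their *orderings*
(afternoon ≥ morning; combined model ≥ single items) instead.

## Problem sizes and runtime choices

Monte-Carlo checks use sizes at which their bands are decisive yet the
suite stays light: 1000 participants for marginal medians, 50
replicates of n = 500 for the chance-level AUC band, 20 replicates of
n = 500 for selection recovery, 200 replicates for null retention, 10
replicates of n = 300 for the session-accuracy ordering. Seeds are
fixed in tests; the acceptance script derives all of its seeds from the
single `--seed` argument via `numpy.random.SeedSequence`.

## Known limitations

- The latent model is single-factor; it cannot express, say, a
  participant with high intake but concentrated urine from heavy sweat
  loss except through the dispersion term.
- Logistic fits under separation report penalized-IRLS coefficients
  whose standard errors are not interpretable (the fit is flagged).
- The colour chart is a synthetic breakpoint table aligned with the low
  USG cut-off, not a colourimetric calibration of any physical chart.
- Timestamps are timezone-naive local clock times, as in the emulated
  protocol; cohorts spanning clock changes are not modelled.
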