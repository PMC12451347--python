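# Methods

## Study design implemented

The package operationalises an event-anchored windowed cohort design for
VKA (vitamin K antagonist) users. For a calendar year with Ramadan
starting on date d₂, follow-up spans [d₀, d₅) with d₀ = d₂ − 60 days and
five contiguous half-open 30-day windows indexed −2…+2; window 0 =
[d₂, d₂ + 30). Because Ramadan lasts 29–30 days, the window-0 end is the
Ramadan end date plus one or more days — the constant 30-day width is what
keeps windows comparable. Ramadan calendar dates are configuration (a
bundled 2013–2019 Gregorian table, overridable by YAML), not computed from
the lunar calendar.

Subjects are prevalent users: included if aged ≥18 at d₀ with a single VKA
episode covering the whole run-in [d₀ − 60 d, d₀] (treatment started ≥2
months before Ramadan). Exclusions, in fixed order with each subject
counted once at the first failing rule: no VKA dispensing within 183 days
before d₀; any DOAC dispensing in that interval; VKA type other than
acenocoumarol/phenprocoumon; missing target range at the last pre-d₀ INR.
Where a subject is eligible in several calendar years, one is drawn
uniformly with a per-subject hash-keyed RNG substream, so the draw is
reproducible and independent of cohort composition and ordering.

Follow-up ends at the first of: d₅, first DOAC dispensing ≥ d₀, clinic-
recorded DOAC use, end of the d₀ episode (discontinuation), first clinical
event of interest, or death. Same-day ties resolve death > clinical event >
DOAC dispensing > clinic DOAC record > discontinuation — the outcome with
analytic consequence wins. Events strictly before d₀ never censor. A
subject whose terminal event lands exactly on a window start is kept at
risk in that window and contributes half a day, so the event is counted
rather than silently dropped; censoring (non-event) exits on a window
start remove the subject from that window's risk set.

## Quality metrics

One anchor-set convention drives all per-window calculations: the anchors
of a window are its in-window INR measurements plus, if present, the
latest measurement of the previous 30-day period (for the first window,
the 30 pre-follow-up days). A window is *eligible* when a VKA episode is
active at its start, follow-up has not ended, and it holds ≥2 in-window
measurements or ≥1 plus the borrowed anchor. Ineligible subject-windows
carry missing (not zero) metrics.

* **Rosendaal TTR/TBR/TAR.** Linear interpolation between consecutive
  anchors; the trajectory is clipped to [window start, min(window end,
  follow-up exit, last anchor)] — no carry-forward beyond the last
  measurement — and partitioned by exact crossing-time solutions. INR
  values exactly on a range limit count as in range (the standard
  convention; configurable). The denominator is covered time, so
  TTR + TBR + TAR = 100 exactly; a `full_window` denominator variant is a
  config switch. No maximum-gap cap is applied: gaps cannot exceed ~60
  days inside a 30-day window with a previous-period anchor. Zero covered
  time (single anchor on the window boundary) yields missing values.
* **VGR.** Mean squared INR change per unit time over consecutive anchor
  pairs, VGR = (1/n) Σ (ΔINR)²/Δt. The literature leaves the constant
  underdetermined, so the time unit is a config switch (`weeks`, the
  default, or `days`) and the divisor is the number of pairs n.
* **Proportions.** Measurement-count fractions over in-window values only
  (the borrowed anchor interpolates but is not counted); boundary INRs
  count as within range; ≥5 and ≥8 are inclusive.
* **Dose changes.** A clinically relevant adjustment is a ≥10% relative
  change between the recommended average daily doses at two consecutive
  visits, inclusive at the threshold (a 1e-9 epsilon keeps decimal doses
  such as 2.00 → 1.80 on the inclusive side of floating-point rounding).
  A window is flagged if any of its anchor pairs with both doses present
  qualifies; pairs with a missing dose are skipped.
* Measurements dated on/after the follow-up exit are excluded throughout:
  post-censoring INRs are not treatment under observation.

## Outcome estimation

Each window restarts the clock at its start with the still-in-follow-up
subjects as the risk set; durations are capped at 30 days. Outcomes are
class sets: composite (bleeding + arterial + venous thromboembolism),
bleeding, arterial thromboembolism, and all-cause mortality. The 30-day
cumulative incidence uses the Aalen–Johansen estimator (lifelines) with
other event classes and death competing; with no censoring and no
competing events before day 30 it reduces exactly to events/at-risk, which
is what makes the published per-window worked examples arithmetically
forced by their counts. CIs are complementary-log-log transforms of the
point estimate with the estimator's variance — chosen because they respect
the [0, 1] boundary; the source analyses do not state their CI method for
cumulative incidence. Mortality is 1 − Kaplan–Meier survival with
Greenwood-variance intervals. Incidence rates are first events over
person-time (365.25 days/year) with exact Poisson CIs from chi-squared
quantiles. Exact intervals over-cover by construction for small counts —
their true two-sided coverage at an expectation of 5 events is 0.98, not
0.95 — which is the price of the guaranteed ≥95% level.

Tied event times are handled by lifelines' deterministic jitter (fixed
seed); at the 30-day evaluation point the estimate is unaffected.

## Period model

yᵢⱼ = β₀ + Σₚ βₚ·1[window j = p] + bᵢ + εᵢⱼ, bᵢ ~ N(0, σ_b²),
εᵢⱼ ~ N(0, σ²), REML via statsmodels MixedLM; window −2 is the reference
and missing subject-windows are omitted row-wise. CIs are Wald with the
normal 1.96 quantile (no df correction) — appropriate at the cohort sizes
this design targets. On balanced complete data the REML fixed effects
equal raw window-mean differences, which the tests exploit as an exact
oracle. Bounded metrics (percentages) are modelled on the raw scale, so
coefficients read as percentage-point differences. All-identical inputs
short-circuit to the degenerate σ² = 0 solution with a flag instead of a
failed optimisation.

## Synthetic cohort generator

The generator emulates what the analysis needs from a clinic registry and
no more:

* **Visit schedule**: renewal process with lognormal gaps (median 16 d,
  log-SD 0.55 → IQR ≈ 11–23 d), started 90 days before d₀ so pre-baseline
  history exists; gaps are rounded to whole days with a 1-day floor.
* **INR process**: observed INR = mid + bᵢ + δ·1[date ∈ window 0] + dᵢₖ,
  where mid is the target-range midpoint, bᵢ ~ N(0, 0.30²) a subject
  offset, and dᵢₖ an AR(1)/OU deviation with stationary SD 0.55 and 5-day
  half-life, floored at 0.8 (physiological minimum). The marginal is
  N(mid + δ·1[w0], √(0.30² + 0.55²)) — total SD 0.63 gives ~21% tails on
  the standard 1.0-wide ranges and TTR in the 50s, matching the order of
  routine-care control. The injected shift δ enters the measurement mean
  directly (not through the lagged deviation), so it is fully expressed
  from the first window-0 visit; that makes the closed-form tail
  difference Φ̄((hi − mid − δ)/σ) − Φ̄((hi − mid)/σ) an exact oracle for
  the above-range proportion shift. Observed INRs are not rounded to one
  decimal as real assays are — rounding would blur that oracle; this is a
  deliberate departure from registry realism.
* **Dosing feedback**: the recommended dose starts lognormal (median 2
  tablets/day) and at each out-of-range visit is multiplied by 1 ∓ step,
  step ~ U(0.10, 0.20), with probability 0.12 — calibrated to ~4%
  per-window dose-reduction flag prevalence under the null. Dose does not
  feed back into the INR process; the feedback exists to give the flags a
  known, INR-coupled prevalence, not to model pharmacokinetics.
* **Events**: independent exponential first-event times per class
  (bleeding 0.0020, arterial 0.0020, venous 0.0008 per 30 d → composite
  ≈ 4.8 per 1000 per 30 d), death competing at 0.0050 per 30 d, DOAC
  switch 0.003 and discontinuation 0.004 per 30 d. Hazards are stationary,
  so the null cohort is a negative control by construction.
* **Determinism**: subject i draws from `default_rng([seed, i])`; growing
  the cohort never reshuffles existing subjects, and a fixed seed
  reproduces output bytes.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: dose–INR pharmacodynamics, seasonal or
secular trends, measurement rounding, target-range changes over time,
informative censoring, event-rate dependence on INR control, and
within-subject scheduling reactivity (sooner revisits after an extreme
INR). The end-to-end checks demonstrate that the pipeline recovers effects
it injects and stays flat when none exist; they cannot validate the
clinical realism of any particular registry.

## Numerical and reporting choices

* Dates are ISO-8601; every interval is half-open [start, end); same-day
  duplicate INRs are rejected at ingest (clinics record one result per
  visit).
* Degenerate inputs return missing values rather than raising wherever
  the quantity is genuinely undefined (empty windows, zero covered time,
  empty risk sets); true contract violations (non-positive INR, T ≤ 0,
  unordered dates) raise.
* Small-cell masking: counts in (0, 10) display `<10`; zero is not
  disclosive and stays. In rows with published totals a single masked cell
  is back-calculable, so the next-smallest positive cell is co-masked.
  The exact co-masking algorithm used by statistical agencies is
  unpublished; next-smallest-cell masking is one defensible realisation.
  Derived columns (rates, incidences) of masked cells are blanked too.
* Monte-Carlo problem sizes in the test suite (e.g. 20 null replicates at
  the full cohort size, 200 period-model replicates at n = 500, 50
  injected-shift replicates at n = 2000) were chosen to keep the
  whole-suite runtime modest while leaving the checks' MC error well below
  the tolerances they assert.
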