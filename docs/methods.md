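# Methods

## Back-calculation model

The modified Fry model expresses the length of a fish at annulus age *i* as
an interpolation in double-log space between two anchors on the allometric
body–otolith curve `L = a + b·R^c`:

```
L_i = a + exp( ln(L0p − a) + [ln(Lcpt − a) − ln(L0p − a)] ·
               [ln(R_i) − ln(R0p)] / [ln(Rcpt) − ln(R0p)] )
```

Assumptions: otolith radius grows monotonically with body length; the
population-level relation between the two is a shifted power law whose
intercept `a` (the "biological intercept") is shared by all fish; each
fish's own trajectory of `ln(L − a)` against `ln R` is close enough to
linear between formation and capture for log-linear interpolation to hold.
When the data lie exactly on the allometry the interpolation is exact — the
package's generative tests verify recovery to < 1e-6 relative error — and
the model accommodates individual departures by forcing every fish's curve
through its own capture point.

### Estimation choices

- **Allometric constants** `(a, b, c)` are fitted by nonlinear least squares
  of capture length on capture radius over the pooled sample (both statuses:
  the intercept is a property of the species, not of protection status).
  Initialisation is a log-linear regression of `ln(Lcpt − a0)` on `ln Rcpt`
  with `a0 = 0`; the joint refinement is bounded by `a < min(Lcpt)` so every
  log argument stays positive. Non-convergence falls back to a straight line
  (`c = 1`) with a warning. Fewer than 5 fish, or (near-)constant capture
  radii, are refused as unidentifiable. Overrides for `a`, `L0p`, `R0p`
  accept literature-derived anchors.
- **Anchors.** `R0p` is the arithmetic mean first-annulus radius of the
  analysed sample; `L0p` defaults to the allometric prediction `a + b·R0p^c`,
  keeping the left endpoint on the fitted curve. A `per_fish` mode anchors
  each fish at its own first annulus instead (the fish-specific convention of
  the original back-calculation literature); the population-mean convention
  is the default because the formation anchor is defined as a mean radius.
- **Capture-age observation.** A fish of age A contributes observations at
  ages 1..A using `R_i = r[i]` — including `r[A]`, the radius at the last
  annulus's formation, not the capture radius. (At `R_i = Rcpt` the formula
  returns the capture length identically; that variant is available via
  `use_capture_radius_at_final_age` for sensitivity.)
- **Invalid records are skipped, not clamped.** A fish whose capture length
  falls below the fitted intercept would need a negative log; clamping it
  would bias length-at-age downward, so it is dropped with a logged reason.

## Year-class labelling

The last annulus of every fish formed in the year before capture; earlier
annuli count back one year each: `year(i) = (capture_year − 1) − (A − i)`.
For a survey captured in year Y covering ages 1..A_max this spans
`[(Y−1) − (A_max − i), Y−1]` at age *i* — 2003–2014 at age 1 down to
2012–2014 at age 10 for a 2015 survey with A_max = 12 — and gives the year
factor `A_max − i` degrees of freedom at age *i* when all ages are present.
Year classes are therefore annulus-*formation* years; a birth-year rule
(`capture_year − A`, constant within a fish) is provided for sensitivity.
Multi-campaign files are handled by applying the rule per fish, with a
warning.

## Statistical model

Per age cohort: `length ~ C(status) + C(year)`, ordinary least squares,
**Type II** sums of squares. The design is unbalanced (year-class sizes vary
widely), and no interaction is fitted: many status × year cells contain at
most one observation, and the scientific questions are the two marginal
effects. Types I/III (III with sum-to-zero contrasts) are available behind
`ss_type` for sensitivity. Gating rules: a cohort with a single year class,
a single status, residual degrees of freedom below 1, or status perfectly
nested in year is returned with a diagnostic gate instead of statistics.

**A posteriori power** of the status test: partial
`η² = SS_status / (SS_status + SS_resid)` converted to Cohen's
`f² = η² / (1 − η²)`, with noncentrality `λ = f²·(u + v + 1)` and
`power = P(F'(u, v, λ) > F_crit(α, u, v))`. At `f² = 0` power equals α by
construction. The `(u + v + 1)` convention is the standard general-linear-
model one; validation against Monte-Carlo rejection rates shows agreement
to a few hundredths, the residual gap reflecting that the convention
approximates the exact design-dependent noncentrality.

p-values are reported unadjusted across ages — the per-age tests are the
analysis's native convention — with a Holm-adjusted status column appended
as a clearly-labelled extension.

**Descriptive summary.** Per age: MR/FR means, standard errors
(`sd/√n`, undefined at n = 1), absolute difference `|m_MR − m_FR|`, and
percent difference `100·|m_MR − m_FR| / ((m_MR + m_FR)/2)` — the midpoint
denominator is the unique convention consistent with the full set of
published mean/difference pairs this implementation replicates.

## LOESS

Locally weighted polynomial regression, degree 2 by default (degree 1 by
flag), tricube weights over the nearest `⌈span·n⌉` points, default span
0.95 to emphasise broad-scale trends. Duplicate x values (many observations
per year) are handled naturally by the distance-based weights. **Convention:
span ≥ 1 disables locality entirely** (uniform weights, one global
polynomial), so span 1 with degree 1 is ordinary least squares; this keeps
the smoother's limiting behaviour unambiguous. Pointwise bands are
approximate t-intervals from the equivalent-kernel rows `l(x0)`:
`fit ± t(0.975, δ)·σ̂·‖l(x0)‖` with `σ̂² = RSS/δ`,
`δ = n − 2·tr(H) + tr(HHᵀ)`. Ages with fewer than 3 distinct year classes
are gated and produce no panel.

## Synthetic-data generator

The generator emulates the single-campaign survey design the pipeline
targets: capture year 2015, ages 1–12, per-status age counts defaulting to
the survey's observed structure (111 MR / 159 FR fish, quota-sampled so the
counts are exact; multinomial sampling optional).

- **Growth**: individual von Bertalanffy curves. Defaults `Linf = 100 mm`,
  `K = 0.2 /yr`, `t0 = −1.3 yr` solve the observed mean lengths at the age
  extremes (≈37 mm at age 1, ≈93 mm at age 12) for a small acanthurid;
  `cv_Linf = 0.10` gives within-age spreads comparable to the observed
  standard errors.
- **Protection effect**: growth increments accrued at ages inside a window
  (default 3–6) are multiplied by `status_effect` (default 1.25) for MR
  fish. Applying the factor to increments guarantees monotone lengths for
  any window and reproduces the observed pattern: early phenotypic
  similarity, mid-life divergence, and a persistent absolute difference at
  late ages whose statistical significance fades as sample sizes shrink.
- **Year trend**: `Linf` increases by 2 mm per birth year (additive),
  detectable at the survey's sample sizes as positive year effects in the
  young, well-populated cohorts.
- **Allometry**: true lengths are mapped to annulus radii by inverting
  `L = 5 + 50·R^1.2` (radii ≈ 0.7–1.8 mm, realistic sagitta scale).
  Multiplicative lognormal noise (sd 0.05) on radius *increments* is
  re-cumulated, preserving strict monotonicity at any noise level. The
  capture radius inflates the last annulus by 5% marginal growth; capture
  length is the allometric value at that radius times a lognormal factor
  (cv 0.03).

What the generator does **not** emulate: site-level heterogeneity within a
status (sites are labels only), size-selective sampling, ageing error,
fractional (sub-annual) growth, and within-fish correlation of the
back-calculated series beyond what the shared growth curve induces. Passing
tests therefore demonstrate correctness of the pipeline's arithmetic and
calibration under idealised sampling, not robustness to those field
realities.

## Problem sizes used in validation

Calibration experiments use small balanced surveys (40 fish per status,
ages 1–6 uniform, noise-free otoliths) so the true effect size is known in
closed form: the type-I experiment runs 1000 replicates (tests) / 400
(acceptance script), the power comparison 600 / 400, and the qualitative
pattern check 25 replicates of the full default survey. Tolerances are three
binomial standard deviations, plus a 0.02 margin where predicted power's
noncentrality convention is itself approximate.

## Known limitations

- Back-calculated observations from the same fish enter several age cohorts
  and are treated as independent within each cohort analysis; no
  mixed-effects correction is attempted (the per-age tests mirror the
  survey analysis convention; a fish-level random effect would be the
  natural extension).
- The ANOVA is classical OLS: heteroscedasticity between statuses (e.g. a
  multiplicative effect scales the MR variance) is not modelled.
- The allometry estimation route and the exact sums-of-squares convention of
  the original survey analysis are not documented; Type II and the pooled
  nonlinear fit are this package's choices, with sensitivity flags to
  explore alternatives against deposited data.
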