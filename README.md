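# otolithbc

Back-calculation of fish length-at-age from otolith annuli, and the
spatiotemporal comparison of protected (marine reserve, MR) versus fished
reef (FR) populations that a single no-take-compatible sampling campaign
makes possible.

Marine reserves usually cannot be sampled repeatedly, so their effect on
body-size distributions is hard to measure directly. Sagittal otoliths
("ear stones") solve this: they accrete one ring (annulus) per year, so a
fish caught once carries its whole growth history. This package implements
that workflow end to end for surveys like a 2015 collection of the brown
surgeonfish *Acanthurus nigrofuscus* across five Philippine marine reserves
and adjacent fished reefs:

1. **Back-calculation** of the standard length at every annulus age with the
   modified Fry model (MFBC);
2. **Cohort assembly** — pooling the per-annulus observations into per-age
   datasets labelled by calendar year class;
3. **Statistics** — per-age two-way ANOVA of length on protection status and
   year class (Type II sums of squares for the unbalanced design), with a
   posteriori power of the status test;
4. **Visualisation** — LOESS regressions of length against year class by
   status, with 95% pointwise confidence bands;
5. A **synthetic-data generator** with known ground truth (von Bertalanffy
   growth, allometric body–otolith coupling) so every stage is testable.

## The model

The MFBC back-calculated length of a fish at age *i* is

```
L_i = a + exp( ln(L0p − a) + [ln(Lcpt − a) − ln(L0p − a)] ·
               [ln(R_i) − ln(R0p)] / [ln(Rcpt) − ln(R0p)] )
```

where `Lcpt`, `Rcpt` are length and otolith radius at capture, `R_i` the
otolith radius at annulus *i*, `R0p` the mean radius of the first annulus,
`L0p` the length at increment formation, and `a` the biological intercept of
the allometric body–otolith relation `L = a + b·R^c`. The formula
interpolates `ln(L − a)` linearly in `ln R` between the formation and
capture anchors; when the population grows exactly on the allometry the
interpolation is exact. `a`, `b`, `c` are fitted by pooled nonlinear least
squares of `Lcpt` on `Rcpt`; `L0p` defaults to the allometric prediction at
`R0p`. See `docs/methods.md` for estimation details, conventions and
limitations.

## Worked example

```python
from otolithbc import (SimConfig, simulate_population, fit, back_calculate_all,
                       add_year_labels, pool_by_age, analyze_cohorts, summary_table)

records, truth = simulate_population(SimConfig(), seed=1)   # 111 MR + 159 FR fish
params = fit(records)
print(f"allometry: a={params.a:.2f} b={params.b:.2f} c={params.c:.3f} "
      f"R0p={params.R0p:.3f} L0p={params.L0p:.2f}")
obs = add_year_labels(back_calculate_all(records, params))
datasets = pool_by_age(obs)
results = analyze_cohorts(datasets)
print(results[["age", "n", "gate", "status_F", "status_p", "power",
               "year_F", "year_p"]].round(3).to_string(index=False))
```

prints

```
allometry: a=-0.32 b=55.38 c=1.110 R0p=0.784 L0p=41.95
 age   n                gate  status_F  status_p  power  year_F  year_p
   1 270            analyzed     2.877     0.091  0.396   3.524   0.000
   2 209            analyzed     0.472     0.493  0.106   2.670   0.004
   3 160            analyzed     8.427     0.004  0.827   2.417   0.014
   4 121            analyzed    19.194     0.000  0.992   1.357   0.223
   5  90            analyzed    23.365     0.000  0.998   1.680   0.125
   6  61            analyzed    25.054     0.000  0.999   1.050   0.404
   7  34            analyzed    17.668     0.000  0.987   0.870   0.514
   8  24            analyzed    14.691     0.001  0.968   0.617   0.656
   9  20            analyzed    10.169     0.006  0.887   0.486   0.697
  10  15            analyzed     6.078     0.031  0.685   0.154   0.859
  11   6            analyzed     2.274     0.229  0.277   0.345   0.598
  12   3 skipped_single_year       NaN       NaN    NaN     NaN     NaN
```

Reading this: the pooled sample sizes per age (`n`) fall from 270 age-1
observations to 3 at age 12 — every fish contributes one observation per
year it lived, so counts at age *i* equal the number of fish at least *i*
years old. The injected mid-life protection effect surfaces exactly as
intended: no significant status effect at ages 1–2, strong MR > FR effects
at intermediate ages, fading significance (but persistent absolute
difference) in the oldest, smallest cohorts. The positive birth-year trend
drives the year effects in the youngest cohorts. Age 12 is gated because all
of its observations belong to a single year class. The same run from a
shell:

```sh
otolithbc run --seed 1 --out-dir run     # writes fish.csv, obs.csv, counts.csv,
                                         # results.csv, table2.csv, figs/, run.json
```

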