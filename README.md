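# meows

Early-warning-score engines and diagnostic-accuracy evaluation for
postpartum cohorts.

Severe maternal morbidity is rare (a few percent of high-dependency-unit
admissions) but life-threatening, and bedside early-warning charts are the
main screening instrument for it. This package implements, as tested
library code, the full comparison pipeline between two such charts:

* **MEOWS** — the Modified Early Obstetric Warning System, scoring nine
  parameters (respiratory rate, SpO₂, oxygen supplementation, temperature,
  systolic and diastolic blood pressure, heart rate, AVPU consciousness
  level, VAS pain) with 0–3 points each and triaging each observation into
  **green** (total 1–4), **yellow** (total 5–6 *or* any single 3-point
  value) or **red** (total ≥ 7);
* **EWS** — a general adult early warning score over five parameters, with
  a physician-notification threshold at a total ≥ 2 and an emergency
  threshold at a total > 3.

It is written for biostatisticians and clinical-research engineers who
want to reproduce, stress-test or extend warning-score validation studies
without access to the underlying patient records.

## What it computes

A woman's stay is summarised by her *worst* observation under each system.
Each stay-level trigger definition (MEOWS red-or-yellow, red, yellow
(exclusive), green (exclusive), EWS ≥ 2, EWS ≥ 4) is evaluated against the
binary severe-maternal-morbidity label as a 2×2 screening table:

* sensitivity `TP/(TP+FN)` and specificity `TN/(FP+TN)` with exact
  Clopper–Pearson 95% CIs,
* predictive values `PPV = TP/(TP+FP)`, `NPV = TN/(TN+FN)` with
  standard-logit CIs,
  `var(logit PPV) = (1−se)/(se·n₁) + sp/((1−sp)·n₀)`,
* likelihood ratios `PLR = se/(1−sp)`, `NLR = (1−se)/sp` with log-method
  CIs, `SE(ln PLR) = √(1/TP − 1/n₁ + 1/FP − 1/n₀)`.

A seeded synthetic-cohort generator (`meows.synthetic`) emulates the
structure of the published validation cohort — 723 postpartum women
observed 4-hourly for 48 h, 3.3% morbidity prevalence, the published cause
mixture and worst-stratum frequencies — so the whole pipeline is testable
end to end. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from meows import ConfusionMatrix, likelihood_ratios, format_estimate

m = ConfusionMatrix(tp=14, fp=6, fn=10, tn=693)   # "MEOWS red" vs morbidity
plr, nlr = likelihood_ratios(m)
print("PLR:", format_estimate(plr, "ratio"), "NLR:", format_estimate(nlr, "ratio"))
```

prints

```
PLR: 68.0 (28.6-161.5) NLR: 0.4 (0.3-0.7)
```

i.e. a woman reaching MEOWS red during her stay has 68-fold increased odds
of severe morbidity (95% CI 28.6–161.5), while staying below red multiplies
the odds by 0.42.

The same from the shell, on a simulated cohort:

```bash
meows simulate --seed 7 --n 723 --output cohort.csv
meows evaluate --input cohort.csv
```

```
test                 sensitivity      specificity      PPV                NPV              PLR                  NLR
meows_red_or_yellow  92% (73%-99%)    63% (59%-66%)    8% (7%-9%)         100% (98%-100%)  2.4 (2.1-2.9)        0.1 (0.04-0.5)
meows_red            58% (37%-78%)    100% (99%-100%)  82% (59%-94%)      99% (98%-99%)    135.9 (41.8-441.7)   0.4 (0.3-0.7)
meows_yellow         33% (16%-55%)    63% (59%-67%)    3% (2%-5%)         96% (95%-97%)    0.9 (0.5-1.6)        1.1 (0.8-1.4)
meows_green          8% (1%-27%)      57% (53%-61%)    0.7% (0.2%-2.4%)   95% (94%-95%)    0.2 (0.1-0.7)        1.6 (1.4-1.9)
ews_ge2              75% (53%-90%)    61% (57%-64%)    6% (5%-8%)         99% (97%-99%)    1.9 (1.5-2.5)        0.4 (0.2-0.8)
ews_ge4              21% (7%-42%)     98% (96%-99%)    24% (11%-44%)      97% (97%-98%)    9.1 (3.6-22.8)       0.8 (0.7-1.0)
prevalence: 3.3% (24/723)
```

Each row is one trigger definition; the obstetric chart dominates the
general one where it matters (high sensitivity with a low negative
likelihood ratio for red-or-yellow). Cohorts are simulated, so EWS rows
and sampling noise vary by seed while the configured MEOWS operating
characteristics are recovered on average.

`meows reproduce` recomputes the full published accuracy table of the
validation study from the canonical reconstructed counts and prints the
computed and published value of every cell. `meows score` emits
per-observation score totals, and custom band tables can be supplied as
YAML (`--tables`); the built-in charts ship as
`src/meows/tables/{meows,ews}.yaml`.

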