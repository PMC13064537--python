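# rvikit

Visit-regularity analysis for end-of-life claims cohorts.

Family physicians deliver most outpatient care in the last years of life, but
classical continuity-of-care indices measure *who* provides care (concentration
across providers), not *when* it happens. The **relative variance index (RVI)**
scores the temporal regularity of a patient's outpatient visits from the
dispersion of the durations between consecutive visits. For inter-visit gaps
g₁…gₙ (in days),

```
cv  = sd(g) / mean(g)        (sample SD, n−1 denominator)
RVI = 1 / (1 + 100 · cv)
```

so RVI = 1 means perfectly even spacing and values near 0 mean highly
irregular visiting. The factor 100 makes the index very sensitive: five
30-day gaps score 1.0, while four 30-day gaps and one 31-day gap score 0.40.

`rvikit` implements, as a tested and reusable pipeline, a death-anchored
analysis of this index for decedents with cardiorespiratory conditions
(advanced COPD and/or heart failure):

- **synthetic claims generator** (`rvikit.synthetic`) — demographics and
  comorbidity marginals, gamma-renewal visit histories with controllable
  inter-visit dispersion and optional near-death clustering, and last-month
  outcomes drawn from configurable negative-binomial / logistic generative
  models, so the whole pipeline is testable without restricted data;
- **regularity scoring** (`rvikit.regularity`) — half-open, death-anchored
  observation windows (default: the two years before death truncating the
  final 30 days), per-patient RVI for the attached family physician and for
  all specialists pooled, empirical quintile categorization, and look-back
  window sensitivity analysis;
- **cohort building** (`rvikit.cohort`) — eligibility filters (age 19–104 at
  death, continuous insurance, community-dwelling, ≥2 FP visits in the
  exposure window) with an exact attrition report, formal/virtual physician
  attachment, and the direct-care specialist claim filter;
- **outcome models** (`rvikit.models`) — statsmodels-style
  `OutcomeModel.from_dataframe(table, spec).fit()` returning an
  `OutcomeResults` with ratio-scale estimates (IRR/OR), Wald 95% CIs, AIC,
  `summary()` and `plot_forest()`; plus Pearson correlations among
  utilization measures and base-vs-specialist-adjusted AIC comparison;
- **pipeline and CLI** (`rvikit.pipeline`, `rvikit` command) — seeded,
  manifest-hashed runs: `generate`, `build-cohort`, `score`, `fit`,
  `sensitivity`, `run-all`, `report`.

## Worked example

```python
>>> from rvikit import compute_rvi
>>> compute_rvi([30, 30, 30, 30, 30]).rvi
1.0
>>> round(compute_rvi([30, 30, 30, 30, 31]).rvi, 2)
0.4
```

A patient whose five inter-visit intervals are all 30 days scores perfect
regularity; moving a single visit by one day drops the score to 0.40 — one
reason the raw index must be used through within-cohort quintiles.

A full seeded run on a 2,000-patient synthetic cohort:

```bash
rvikit run-all --seed 7 --outdir runs/demo
rvikit report --outdir runs/demo
```

prints (excerpt):

```
=== Cohort profile (median (P25, P75) / %) ===
Age at 2 years before death: 80 (70, 87)
Male: 54.5%
Homecare: 76.3%
ADG count: 13 (11, 16)

=== Utilization and regularity ===
FP visits in window: 9 (7, 11)
Specialist visits in window: 12 (10, 14)
FP RVI: 0.0123 (0.0102, 0.0149)

=== Window sensitivity (median (P25, P75) RVI) ===
window    730-30: 0.0123 (0.0102, 0.0149), n=1999
window   730-365: 0.0137 (0.0107, 0.0198), n=1921
```

The cohort median RVI (~0.012) shows that end-of-life visiting is highly
irregular — even the most "regular" quintile sits far below 1 — and the
window rows show how strongly the score depends on the chosen look-back
period. The adjusted-effects table in the same report gives each quintile's
IRR/OR versus Q1 with 95% CIs; at this demo size the intervals are wide, and
the generative effect sizes (top-quintile IRR 1.07 on hospitalizations, 1.06
on ED visits, OR 1.30 on acute-care death; homecare IRR 0.50 on ED visits)
are recovered precisely in the 20,000-patient replicated experiments below.

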