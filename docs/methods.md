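# Methods

This note documents the models and procedures implemented in `rvikit`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## The regularity index

For a patient's distinct outpatient visit days inside an observation
window, the inter-visit gaps g₁…gₙ (days) are summarised by

    cv  = sd(g) / mean(g)      (sample standard deviation, n−1 denominator)
    rvi = 1 / (1 + 100 · cv)

The implemented rule is a calibrated reconstruction: it reproduces both
published worked examples exactly — five 30-day gaps give 1.0, and
(30, 30, 30, 30, 31) gives 0.40309…, printed as 0.40 (an n-denominator SD
would give ≈0.43 and is therefore rejected) — and it yields the observed
cohort median of ≈0.011 under near-exponential visiting, since
1/(1 + 100·0.9) ≈ 0.011. Properties, all covered by tests:

- scale invariance: rvi(c·g) = rvi(g) for any c > 0;
- shift invariance: translating all visit days (while they stay in-window)
  leaves the score unchanged;
- order invariance: the statistic ignores the *sequence* of gaps — a
  limitation of the index, since slowly lengthening gaps and alternating
  short/long gaps can score identically (gaps are sorted internally, which
  also makes permutation invariance bit-exact);
- perturbing a single gap away from the common value strictly lowers the
  score, which is why a one-day deviation collapses 1.0 to 0.40.

Degenerate case: a patient with exactly two in-window visits has one gap
and an undefined variance. Such patients are retained (the eligibility
rule excludes only those with fewer than two visits) with rvi = 1.0, cv = 0
and a `degenerate` flag, so analysts can filter them explicitly.

## Windows, visits, and quintiles

Observation windows are half-open, day-granular and death-anchored:
`ObservationWindow(start, end)` covers offsets `end < d ≤ start` days
before death, so with the default (730, 30) a visit exactly 30 days before
death is excluded ("truncating the final 30 days") and one exactly 730
days before death is included. Sensitivity windows: (730, 90), (730, 365),
(365, 90).

Outpatient visits are claims whose location code is Office, Home or Phone;
same-day duplicate claims collapse to a single visit day (zero gaps would
make the cv explode). Family-physician scores use only the attached
physician's claims; specialist scores pool all direct-care specialists
into one timeline. Attachment is the roster entry when present, otherwise
the FP with the most outpatient claims in the (1460, 730] attribution
window, ties broken to the smallest physician id (flagged); patients with
neither are excluded with their own attrition line.

Scores are cut at the cohort's 20/40/60/80th percentiles
(linear-interpolation definition) into quintiles Q1 (least regular) … Q5;
scores tied with a cut point fall into the lower quintile. Quintiles are
cohort-relative by construction — scores from different cohorts or windows
are not comparable, which is a documented limitation of the index.

## Synthetic cohort generator

The generator's defaults are the study conditions: 55.3% male, median age
80 (71, 87) at two years before death, 12.7% rural, income-quintile shares
(25.1, 22.7, 19.4, 16.9, 15.9)%, 76.4% homecare, 35.1% cancer, median 13
(11, 16) aggregated diagnosis groups (ADGs), subgroup shares 18.2 / 13.0 /
68.8% (ACOPD&HF / ACOPD / HF), ~9 FP and ~12 specialist visits per default
exposure window, inter-visit cv 0.9, death dates uniform over 2017–2019.

Ages and ADG counts are drawn from a *split* lognormal matched exactly to
the median and both quartiles (a single-sigma lognormal cannot fit the
asymmetric quartile pair); ages are clipped to 19–102 at two years before
death so that every clean patient passes the age filters — attrition is
driven solely by deliberately injected violations, which the
`inject_exclusion_cases` helper tags with their ground-truth rule.

Visit histories follow a gamma renewal process: gaps are i.i.d.
gamma(shape = 1/cv², scale = mean-gap/shape), which nests exponential
visiting (cv = 1) and near-regular visiting (cv → 0) and hits the target
visit count in expectation. FP histories span the full (1460, 0] range —
at the daily intensity implied by `fp_visit_rate` per exposure window — so
the attribution window has claims; specialists span (730, 0]. Arrival
times are rounded to the *nearest* whole day (floor would wobble ±1 day
for arrivals sitting exactly on integer boundaries in the cv → 0 limit,
destroying the exact-regularity limit) and duplicates collapse. Patients
drawn with fewer than two exposure-window FP visits are redrawn (a
deterministic fallback guarantees the floor).

`clustering_near_death` ≥ 1 compresses gaps in the final 90 days before
death by time-rescaling (the last 90 days are traversed at 1/multiplier
speed), emulating the intensification of outpatient care near death. The
default is 1 (stationary visiting); the window-sensitivity analysis is
exercised with clustering 3.

Outcomes are drawn from the generative inverse of the analysis models:
negative binomial (log link, NB2: variance μ + αμ², default α = 0.3,
counts capped at 10 as a guard against pathological draws) for last-30-day
hospitalizations and ED visits, Bernoulli (logit link) for acute-care
death. The default coefficients are the published adjusted estimates —
top-quintile IRR 1.07 (hospitalizations) and 1.06 (ED), OR 1.30
(acute-care death); homecare 0.96 / 0.50 / 0.83 — with intermediate
quintiles ramping linearly, zero specialist-regularity effects, and modest
covariate effects in the reported directions. The design matrix of the
generative model is identical to the fitted one (quintile and income
dummies, linear age/ADG/visit-count terms); covariate columns are centred
at their empirical means in the linear predictor so the configured
baselines (0.8 hospitalizations, 0.9 ED visits, P(acute-care death)
0.617) remain cohort-level values. Because the generative and fitted
designs coincide, refitting recovers every coefficient up to Monte-Carlo
error — the pipeline's central validation property.

What the generator does **not** emulate: patient-level visit-rate
heterogeneity (the renewal process at a common rate gives a visit-count
IQR of roughly (7, 11), narrower than the observed (5, 15)), correlation
between comorbidity and visiting, physician-level clustering of patients,
calendar-time billing trends, or cause-of-death structure. Passing tests
therefore establish the *internal* consistency of the pipeline under its
stated generative model, not the realism of any particular marginal
beyond those listed above.

Two small regime facts worth knowing. First, the cohort median RVI under
the defaults simulates to ≈0.0124 rather than the asymptotic
1/(1 + 100·0.9) ≈ 0.0110, because the sample cv of ~8 gaps is biased
below its asymptote; both values sit inside the 0.009–0.013 band the
analysis targets. Second, patients whose pooled-specialist score is not
computable (fewer than two in-window specialist visit days) enter the
sensitivity model at the reference level Q1, consistently in generation
and fitting.

## Outcome models

Counts are fitted with `statsmodels` negative binomial regression (NB2,
dispersion α estimated by maximum likelihood from a Poisson warm start,
BFGS with gtol 1e-8); the binary outcome with logistic regression. A
solution whose convergence flag is unset but whose score vector is
numerically zero (max |score| < 0.01) is accepted — this arises only at
the α → 0 boundary on equidispersed data, where the coefficients agree
with a Poisson fit to < 1e-4. Estimates are exponentiated to IRR/OR with
Wald 95% CIs (exp(β ± 1.96·SE)); profile intervals were not implemented,
matching standard reporting practice for large administrative cohorts.
Exposure reference is Q1; age enters linearly; income and RVI quintiles
are unordered categories; missing values in modelled columns are rejected,
never imputed (administrative completeness is assumed). The covariate set
includes homecare receipt and cancer prevalence so their adjusted effects
are estimable alongside the exposure. No offset/exposure term is used for
the fixed 30-day outcome window.

The sensitivity model adds the pooled-specialist RVI quintiles; model
comparison reports AIC(base) − AIC(sensitivity). With zero generative
specialist effect the difference is bounded by the parameter penalty
(|Δ| ≤ 8 for four added parameters, up to the usual χ²₄ fluctuation).
Pearson correlations among the per-patient measures (FP RVI, specialist
RVI, visit counts, unique specialists) report NaN — never a silent 0 —
for zero-variance columns.

## Pipeline reproducibility and problem sizes

A single run seed is expanded into fixed per-stage substreams
(`SeedSequence([seed, stage_id])`), so stage order cannot perturb
downstream randomness; every CSV artifact records the seed in a header
comment and the run manifest stores SHA-256 hashes, which are reproduced
byte-for-byte on rerun. The validation suite uses cohorts of 300–6,000
patients for behavioural tests and 20,000 patients × 20 replicates for the
parameter-recovery experiments; the reproduction script uses the same
20,000 × 20 design per experiment. These sizes give Monte-Carlo standard
errors of ≈0.003–0.008 on the log-ratio scale, an order of magnitude
below the effect sizes of interest.

## Known limitations

- The RVI formula is a calibrated reconstruction pinned to the two printed
  worked examples and the cohort median; the original supplementary
  definition could differ in conventions not identifiable from those
  values (e.g. rounding of 0.40309 to 0.40 versus a different variance
  convention cannot be distinguished).
- The index ignores gap order and is strongly window-dependent; the
  window-sensitivity analysis quantifies the latter but cannot remove it.
- Quintile effects are cohort-relative; estimates are not transportable
  across populations with different interval distributions.
- No physician-level clustering or cluster-robust variance is modelled;
  estimates assume independent patients.
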