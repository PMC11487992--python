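# suicohort

Tools for studying the prevalence, ten-year course, and risk factors of
12-month suicidal ideation (SI) and suicide attempts (SA) among students
in Dutch senior secondary vocational education (MBO), built around a
repeated cross-sectional survey design (school years 2013/2014 through
2022/2023). The original individual-level survey data are not public, so
the package ships a calibrated synthetic-cohort generator that emulates
the study population's structure, and every analysis component is
exercised and validated against it.

It is aimed at epidemiologists and biostatisticians who want to (a)
reproduce the study's descriptive and univariate statistics from its
published marginals, (b) stress-test the heuristic interaction-search
logistic model on data with known ground truth, or (c) run the same
pipeline on their own survey extracts.

## What's inside

- **`suicohort.coding`** — survey variable coding: the Kessler K10
  psychological-distress score (10 items, 1–5, summed to 10–50) banded
  into low (10–15) / moderate (16–29) / high (30–50) risk; SI
  dichotomised never vs any; SA yes/no with "no answer" as missing; age
  clamped to 15…23+ and banded 15–17 / 18–20 / 21–23+; school years
  dichotomised into pre-corona (2013/14–2018/19) and corona
  (2019/20–2022/23); complete-case filtering with a per-reason
  exclusion tally.
- **`suicohort.cohort`** — a seeded generator whose defaults are the
  study conditions: ≈45/55 male/female, age bands ≈59.5/29.9/10.6%,
  gender-specific risk-band margins with a rising high-risk trend
  (10.9% → 24.9%), and Bernoulli SI/SA outcomes from a logistic model
  with the study's final multivariate coefficients. Per-year log-odds
  offsets are calibrated by 1-D root finding so the analytic expected
  prevalence matches the published anchors (SI 17.7% → 23.0%, SA
  2.3% → 3.2%).
- **`suicohort.descriptives`** — prevalence series, contingency tables
  and risk-band distributions with the study's rounding conventions.
- **`suicohort.univariate`** — `UnivariateLogit(...).fit()` →
  per-level odds ratios with Wald 95% CIs and per-variable Bonferroni
  significance (α = 0.05 / number of levels), backed by a hand-written
  Newton–Raphson fitter cross-checked against the closed-form
  contingency odds ratio (a·d)/(b·c).
- **`suicohort.interaction_search`** —
  `InteractionSearchLogit(...).fit()`: the three-phase heuristic model.
  Split 40/10/50 into primary-training / control / validation; greedily
  add the top likelihood-ratio-scoring conjunction feature (2–3 variable
  levels, reference levels allowed) while it clears a threshold T
  (default: the χ²₁ upper 0.1% point, 10.828), with a held-out control
  veto and a considered-list L that bars re-scoring; then refit once on
  the untouched validation half for selection-bias-free estimates.
- **`suicohort.pipeline` / CLI `suicohort`** — end-to-end runs with
  manifests, exclusion tallies, trend series and table-shaped CSVs.

## The model

For student *i* with covariates gender, age band, K10 risk band and
school-year era, outcomes are Bernoulli with

logit P(Yᵢ = 1) = β₀ + β_female + β_{18–20} + β_{21+} + β_moderate +
β_high + β_corona + Σ_f γ_f · 1[i matches feature f] + δ_year

where each β enters only for non-reference levels (reference: male,
<18, low risk, pre-corona), the γ_f are coefficients of discovered
interaction features (e.g. "<18 + high"), and δ_year is the calibrated
per-year offset. The search scores a candidate feature by the
likelihood-ratio statistic 2·(ℓ(model+f) − ℓ(model)) on the primary
training set and accepts it only if the enlarged model also improves
total log-likelihood on the control set.

## Worked example

```python
from suicohort import CohortGenerator, default_config, code_records, filter_complete
from suicohort.interaction_search import InteractionSearchLogit
from suicohort.univariate import univariate_table

gen = CohortGenerator(default_config(n_per_year=20_000)).calibrate()
cohort, _ = filter_complete(code_records(gen.generate(seed=1)),
                            required=("gender", "age", "k10", "si"))

univariate_table(cohort, "risk", "si", levels=("low", "moderate", "high")).summary()
#    level     n  events   pct  odds_ratio  ci_low  ci_high  significant
#      low 65976    2223  3.37        1.00     NaN      NaN        False
# moderate 98528   16829 17.08        5.91    5.65     6.18         True
#     high 35496   21712 61.17       45.17   43.08    47.37         True

res = InteractionSearchLogit(cohort, "si").fit(seed=1)
[f.name for f in res.accepted_features]
# ['<18 + high']
res.summary()
#                 term     n  estimate      t          OR (95% CI)
# B0 (full population) 20382     -3.32 -98.86    0.04 (0.03, 0.04)
#                 male 44871      0.00    NaN             1 (1, 1)
#                  <18 59589      0.00    NaN             1 (1, 1)
#                  low 32977      0.00    NaN             1 (1, 1)
#           pre_corona 59991      0.00    NaN             1 (1, 1)
#               female 55129     -0.13  -6.94    0.88 (0.85, 0.91)
#                18-20 29806      0.13   5.31    1.14 (1.08, 1.19)
#                  21+ 10605      0.04   1.31    1.04 (0.98, 1.11)
#             moderate 49312      1.80  54.48    6.03 (5.66, 6.44)
#                 high 17711      3.74  90.05 41.99 (38.71, 45.54)
#               corona 40009     -0.09  -4.85    0.91 (0.88, 0.95)
#           <18 + high 10473      0.24   6.09    1.27 (1.17, 1.37)
```

The univariate table shows high-distress students with ~45× the odds of
SI of low-distress students; the search, run on a 200,000-record
synthetic cohort generated with a planted under-18 × high-distress
interaction of log-odds 0.24, recovers exactly that feature and the
validation-half refit returns its estimate (0.24, OR 1.27) along with
the other generating coefficients (e.g. female −0.13 vs the generating
−0.15, high risk 3.74 vs 3.76).

Or from the shell:

```bash
suicohort all --out-dir run/ --seed 1 --n-per-year 10000 --plots
```

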