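# Methods

## Study design being emulated

The package models a repeated cross-sectional survey of Dutch
vocational-education (MBO) students: each school year from 2013/2014 to
2022/2023 an independent sample answered a web questionnaire covering
12-month suicidal ideation (SI), 12-month suicide attempts (SA), and the
Kessler K10 psychological-distress scale, alongside gender and age.
Analyses treat each respondent once; there is no within-person
follow-up.

## Variable coding

- **K10.** Ten items scored 1 ("never") to 5 ("always") are summed to a
  10–50 score and banded low (10–15), moderate (16–29), high (30–50);
  all boundaries inclusive. A record with any missing item gets a
  missing score — no prorating, because the analyses are complete-case.
- **SI.** The four-level response (never / occasionally / sometimes /
  often) is dichotomised as *any non-never → yes*. The source
  instrument's dichotomisation wording lists a level ("intermittently")
  that does not appear in its response list ("sometimes"); the
  any-non-never rule satisfies both readings and is the one implemented.
- **SA.** Yes / no / no-answer, with no-answer coded missing. The
  no-answer records are excluded from SA analyses but retained for SI
  analyses (per-outcome complete cases), matching the per-variable Ns of
  the study's univariate table.
- **Age.** Stored as integer years, clamped to 15 and "23 and older"
  before banding (the clamp is applied uniformly to all years). Two
  equivalent band labellings exist: 15–17/18–20/21–23+ for descriptives
  and univariate models, <18/18–20/21+ for the multivariate model; they
  partition ages identically.
- **Era.** School years 2013/2014–2018/2019 are pre-corona,
  2019/2020–2022/2023 corona. Labels in the "2013-2014" dialect are
  normalised to "2013/2014".
- **Exclusions.** Gender "other" (0.2% of the original population, too
  small to analyse) is dropped, then missing required variables, in a
  fixed reason order (gender_other, missing_gender, missing_age,
  missing_k10, missing_si, sa_no_answer, missing_sa); a
  multiply-deficient record is tallied once under the first applicable
  reason, so retained + tallied = input.

## Synthetic cohort generator

The generator's defaults are the study conditions, taken from the
published marginals:

| quantity | default | source |
| --- | --- | --- |
| gender mix | male 0.4486 / female 0.5514 | published counts 44,470 / 54,656 |
| age bands 15–17 / 18–20 / 21–23+ | 0.5947 / 0.2991 / 0.1062 | published counts |
| risk margins, male | 43.14 / 45.32 / 11.50 % | published distribution |
| risk margins, female | 24.40 / 52.79 / 22.77 % | published distribution |
| high-risk trend | 10.9% (2013/14) → 24.9% (final year), linear | published first/last values |
| SI anchors | 17.7% → 23.0%, linear in between | published first/last values |
| SA anchors | 2.3% → 3.2%, linear in between | published first/last values |
| SI coefficients | −3.52, female −0.15, 18–20 0.13, 21+ 0.05, moderate 1.83, high 3.76, corona −0.01, `<18 + high` 0.24 | published final model |
| SA coefficients | −4.66, female −0.35, 18–20 0.22, 21+ 0.26, moderate 0.80, high 2.95, corona −0.23 | published final model |
| SA no-answer rate | 4.8%, missing completely at random | published non-response share |

Design choices where the published record leaves the design open:

- **Risk bands are categories, not a latent item model.** Only band
  margins are constrained, so bands are drawn directly; a K10 score is
  drawn uniformly inside the band so coding round-trips exactly. No
  item-level psychometrics are simulated.
- **Year trend of risk.** Each gender's high-risk share follows the
  linear population trend, scaled so its across-year average equals that
  gender's published margin; the within-gender low:moderate ratio is
  held fixed. Trends interpolate on the year's position within the full
  2013–2023 range, so a configuration covering a subset of years uses
  the same per-year values as the full design.
- **Ages are uniform within band** (21–23+ capped at 25); nothing
  published constrains the within-band shape, and the outcome model only
  sees the band.
- **SI and SA are drawn independently given covariates.** No joint
  model is published. This is a fidelity limitation: real SI and SA are
  strongly dependent, so joint statistics (e.g. SA among ideators) are
  not meaningful in the synthetic data.
- **SA interaction features are omitted from the defaults.** The
  published SA model lists several accepted interaction rows, but all
  are statistically indistinguishable from zero (|t| ≤ 1.23); they are
  artefacts of one search run rather than a defensible generating
  mechanism. Arbitrary composite terms can still be supplied in the
  coefficient map. One published SA row prints an estimate (0.22) and an
  OR (1.02) that contradict each other; the estimate column is used.
- **Calibration.** For each year the additive log-odds offset solves
  E[prevalence] = anchor, where the expectation is computed analytically
  over the year's 18 covariate cells (gender × age band × risk) and is
  strictly increasing in the offset; Brent's method on [−30, 30] with
  xtol 1e-10 leaves the achieved expectation within 1e-8 of the anchor.
  Year offsets, not the era coefficient, carry the secular trend (the SI
  era coefficient is −0.01, effectively absent).

What passing tests on this generator do and do not show: they validate
the *machinery* — coding, estimation, calibration, selection behaviour
with known ground truth — under a covariate structure matched to the
study's margins. They cannot validate substantive conclusions about
real students, because the generator has no item-level structure, no
school clustering, no informative non-response, and no SI–SA
dependence.

## Univariate models

One categorical predictor per model, maximum likelihood via
Newton–Raphson with step halving: convergence when the largest absolute
score component or parameter change drops below 1e-10 (cap 100
iterations). A small L2 ridge (1e-8) engages only when separation is
detected (estimates diverging past |β| = 40); separated data without a
ridge raise an explicit error, and non-convergence is flagged on the
result, never silent. The fitter is cross-checked three ways in the
test suite: the closed-form contingency odds ratio (a·d)/(b·c) with
Wald CI exp(log OR ± 1.959964·√(1/a+1/b+1/c+1/d)); statsmodels'
maximum-likelihood logit; and a 200-replicate coverage simulation.

Inference is Wald-based throughout, chosen because the published
intervals are consistent with Wald intervals on the published counts.
Significance stars use the study's Bonferroni rule literally: α = 0.05
divided by the variable's *total* level count (0.025 for two-level,
0.017 for three-level variables), even though only levels−1 contrasts
are tested.

## Interaction search

Three phases. (1) A uniform random, unstratified 40/10/50 split into
primary training, control and validation sets (largest-remainder
rounding; the published design describes a 50% training half further
split 80/20). (2) Forward search: candidates are all conjunctions of
levels of 2–3 distinct variables — including reference levels, since
the published feature list contains them — excluding features already
in the considered list L and features with fewer than 30 positive
indicators in the primary training set (a separation guard). Each
candidate is scored by the likelihood-ratio statistic of adding it to
the current model, fitted on the primary training set with warm starts.
The maximum (ties: lower order first, then name) is accepted if it
exceeds T and the enlarged model strictly improves total held-out
log-likelihood on the control set; either way it enters L and is never
re-scored. After a control veto the enumeration is restricted to
interactions among variables already in the model — with all four study
variables in the base model this restriction is vacuous, but it is
implemented for generality. (3) The base dummies plus accepted features
are refit once on the validation half; any overlap between validation
and search records raises a hard error.

Numerical and design choices:

- **Scoring rule.** The source algorithm's exact score is defined in
  prior work, not restated; the likelihood-ratio statistic is used
  because it gives T a χ²₁ interpretation. Default T = 10.828 (the χ²₁
  upper 0.1% point) tempers the ~100-candidate multiplicity; with that
  T, the search on null cohorts (no generating interaction, n = 50,000)
  accepted a spurious feature in 1 of 20 seeded runs in the acceptance
  suite.
- **Control metric.** "Improved performance" is implemented as strictly
  greater total log-likelihood on control records; a tie is a veto.
- **Known behaviour.** The control veto is itself noisy: with a real
  but modest effect, roughly one seed in ten vetoes the true top-scoring
  feature, after which L permanently bars it and an equivalent
  reparameterisation (e.g. "18-20 + high" with the opposite sign) may
  enter instead. The acceptance suite's power study (planted
  `<18 + high` at log-odds 0.24, n = 200,000) recovers the exact planted
  feature in 17 of 20 seeds.
- The t-statistics in the validation report are estimate/SE; the Wald
  CI excludes OR = 1 exactly when |t| > 1.959964.

## Problem sizes

The simulation studies use n = 200,000 (10 years × 20,000) for
parameter and interaction recovery — matching the scale at which the
planted 0.24 log-odds interaction is reliably detectable — with 20
seeded replicates; null-search runs use n = 50,000 × 20 seeds; CI
coverage uses 200 replicates at n = 5,000; calibration checks draw
50,000 records per anchored year.

## Known limitations

- Several published table cells are internally inconsistent (two
  percentages disagree with their own counts; some odds ratios are not
  reproducible from the printed counts, implying a different
  complete-case subset for the regressions). Only internally consistent
  cells are used as checks.
- The generator cannot, even in expectation, reproduce the published
  multivariate coefficient values from real data — those require the
  non-public survey records. What the package demonstrates is that its
  estimator recovers whatever coefficients generated the data.
- No survey weights, no school-level clustering, no longitudinal
  linkage — matching the published design, which has none either.
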