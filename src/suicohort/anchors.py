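"""Reference summary statistics of the Dutch vocational-student (MBO)
suicidality survey, school years 2013/2014-2022/2023.

These printed marginals are the study conditions the synthetic-cohort
generator emulates and the inputs to the in-sample descriptive checks:
per-level counts and event counts of the univariate tables, the overall
SI/SA prevalences, the risk-band distribution by gender and age, and the
first/last-year prevalence anchors of the trend figures.
"""
from __future__ import annotations

#: Overall cohort size and event counts (12-month SI / SA).
OVERALL = {"n": 101_182, "si_events": 19_022, "sa_events": 2_833}

#: Univariate table counts: variable -> list of (level, N, SI events, SA events),
#: reference level first.
UNIVARIATE_COUNTS: dict[str, list[tuple[str, int, int, int]]] = {
    "gender": [
        ("male", 44_470, 6_878, 1_153),
        ("female", 54_656, 11_440, 1_545),
    ],
    "age_band3": [
        ("15-17", 59_080, 10_481, 1_471),
        ("18-20", 29_711, 6_024, 887),
        ("21-23+", 10_548, 1_957, 369),
    ],
    "era": [
        ("pre_corona", 45_420, 7_576, 1_193),
        ("corona", 55_762, 11_312, 1_576),
    ],
    "risk": [
        ("low", 33_148, 890, 278),
        ("moderate", 49_889, 7_441, 788),
        ("high", 18_103, 10_553, 1_703),
    ],
}

#: Risk-band distribution (low, moderate, high) by gender, as proportions.
RISK_BY_GENDER = {
    "male": (0.4314, 0.4532, 0.1150),
    "female": (0.2440, 0.5279, 0.2277),
}

#: Risk-band distribution by age band.
RISK_BY_AGE = {
    "15-17": (0.3459, 0.4883, 0.1653),
    "18-20": (0.3009, 0.4991, 0.1999),
    "21-23+": (0.2984, 0.5100, 0.1914),
}

#: First- and last-year prevalence anchors (proportions).
SI_ANCHOR_FIRST, SI_ANCHOR_LAST = 0.177, 0.230
SA_ANCHOR_FIRST, SA_ANCHOR_LAST = 0.023, 0.032

#: High-risk band prevalence in the first and last school year.
HIGH_RISK_FIRST, HIGH_RISK_LAST = 0.109, 0.249

#: Share of respondents choosing "no answer" on the suicide-attempt item.
SA_NO_ANSWER_RATE = 0.048

#: Final multivariate model coefficients (log-odds), estimated on the
#: survey's validation half; used as the generator's default outcome model.
SI_COEFFICIENTS = {
    "intercept": -3.52,
    "female": -0.15,
    "18-20": 0.13,
    "21+": 0.05,
    "moderate": 1.83,
    "high": 3.76,
    "corona": -0.01,
    "<18 + high": 0.24,
}

SA_COEFFICIENTS = {
    "intercept": -4.66,
    "female": -0.35,
    "18-20": 0.22,
    "21+": 0.26,
    "moderate": 0.80,
    "high": 2.95,
    "corona": -0.23,
}
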