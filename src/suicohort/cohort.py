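"""Seeded synthetic vocational-student cohorts.

The generator reproduces the study's covariate structure — gender mix,
three age bands, gender- and year-specific K10 risk-band distributions
with a rising high-risk trend — and draws 12-month suicidal-ideation
(SI) and suicide-attempt (SA) outcomes from a logistic model whose
default coefficients are the survey's final multivariate estimates.
Per-year additive log-odds offsets carry the secular trend; a 1-D root
find calibrates each year's offset so the analytic expected prevalence
(averaged over that year's covariate mixture) hits a target anchor.

Risk bands are generated directly as categories, with a K10 score drawn
uniformly inside the band so that re-coding round-trips exactly; only
the band margins are constrained by the study's tables.  SI and SA are
drawn independently given covariates.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import anchors
from .coding import (
    AGE_BANDS3,
    AGE_BANDS_ML,
    GENDERS,
    K10_BANDS,
    PRE_CORONA_YEARS,
    RISK_LEVELS,
    SCHOOL_YEARS,
    CodingError,
)

__all__ = [
    "PrevalenceAnchor",
    "GeneratorConfig",
    "CohortGenerator",
    "term_indicator",
    "linear_predictor",
    "sample_covariates",
    "sample_outcomes",
    "expected_prevalence",
    "calibrate_year_offsets",
    "generate_cohort",
    "default_config",
    "default_anchors",
    "default_risk_probs",
]

#: Mapping of model-term level labels to (coded column, level) pairs.
LEVEL_TO_VAR: dict[str, tuple[str, str]] = {
    "male": ("gender", "male"),
    "female": ("gender", "female"),
    "<18": ("age_band_ml", "<18"),
    "18-20": ("age_band_ml", "18-20"),
    "21+": ("age_band_ml", "21+"),
    "low": ("risk", "low"),
    "moderate": ("risk", "moderate"),
    "high": ("risk", "high"),
    "pre_corona": ("era", "pre_corona"),
    "corona": ("era", "corona"),
}

_AGE_RANGES = {"15-17": (15, 17), "18-20": (18, 20), "21-23+": (21, 25)}
_BAND3_TO_ML = dict(zip(AGE_BANDS3, AGE_BANDS_ML))
_SI_YES_LEVELS = np.array(["occasionally", "sometimes", "often"])


def term_indicator(term: str, coded: pd.DataFrame) -> np.ndarray:
    """Indicator column (0/1 floats) for a model term on coded records.

    ``"intercept"`` is all ones; a composite term such as
    ``"<18 + high"`` is the product of its level indicators.
    """
    if term == "intercept":
        return np.ones(len(coded))
    out = np.ones(len(coded))
    for part in term.split(" + "):
        part = part.strip()
        if part not in LEVEL_TO_VAR:
            raise CodingError(f"unknown model term level: {part!r}")
        col, level = LEVEL_TO_VAR[part]
        out *= (coded[col] == level).to_numpy(dtype=float)
    return out


def linear_predictor(
    coefficients: dict[str, float],
    coded: pd.DataFrame,
    year_offsets: dict[str, float] | None = None,
) -> np.ndarray:
    """Log-odds per record: intercept + level dummies + interaction
    indicators + the record's school-year offset."""
    if "intercept" not in coefficients:
        raise CodingError("coefficient map must contain an 'intercept' term")
    eta = np.zeros(len(coded))
    for term, beta in coefficients.items():
        eta += beta * term_indicator(term, coded)
    if year_offsets:
        eta += coded["school_year"].map(year_offsets).fillna(0.0).to_numpy(float)
    return eta


@dataclass(frozen=True)
class PrevalenceAnchor:
    """Target SI/SA prevalence (proportions in (0,1)) for one school year."""

    year: str
    si: float
    sa: float

    def __post_init__(self):
        for name in ("si", "sa"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} anchor must lie in (0, 1), got {v}")


def _year_positions(years: tuple[str, ...]) -> np.ndarray:
    """Position of each school year within the 10-year study range,
    scaled to [0, 1]; trends interpolate on these positions so a subset
    of years keeps the same per-year values as the full design."""
    first = int(SCHOOL_YEARS[0][:4])
    span = int(SCHOOL_YEARS[-1][:4]) - first
    return np.array([(int(y[:4]) - first) / span for y in years])


def default_risk_probs(
    years: tuple[str, ...] = SCHOOL_YEARS,
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Gender- and year-specific risk-band probabilities.

    The population high-risk share rises linearly between the first- and
    last-year anchors; each gender's high share is scaled so its
    across-year average matches the study's per-gender margin, and the
    low:moderate ratio within gender is held fixed.
    """
    t = _year_positions(years)
    high_trend = anchors.HIGH_RISK_FIRST + t * (
        anchors.HIGH_RISK_LAST - anchors.HIGH_RISK_FIRST
    )
    hbar = float(high_trend.mean())
    probs: dict[tuple[str, str], tuple[float, float, float]] = {}
    for gender in GENDERS:
        low_g, mod_g, high_g = anchors.RISK_BY_GENDER[gender]
        low_g, mod_g, high_g = (
            v / (low_g + mod_g + high_g) for v in (low_g, mod_g, high_g)
        )
        for year, h_t in zip(years, high_trend):
            high = high_g * h_t / hbar
            scale = (1.0 - high) / (low_g + mod_g)
            probs[(gender, year)] = (low_g * scale, mod_g * scale, high)
    return probs


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_per_year: int = 10_000
    years: tuple[str, ...] = SCHOOL_YEARS
    gender_probs: dict[str, float] = field(
        default_factory=lambda: {"male": 44_470 / 99_126, "female": 54_656 / 99_126}
    )
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: {
            "15-17": 59_080 / 99_339,
            "18-20": 29_711 / 99_339,
            "21-23+": 10_548 / 99_339,
        }
    )
    risk_probs_by_gender_year: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=default_risk_probs
    )
    si_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(anchors.SI_COEFFICIENTS)
    )
    sa_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(anchors.SA_COEFFICIENTS)
    )
    year_offsets_si: dict[str, float] = field(default_factory=dict)
    year_offsets_sa: dict[str, float] = field(default_factory=dict)
    sa_no_answer_rate: float = anchors.SA_NO_ANSWER_RATE
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (
            ("gender_probs", self.gender_probs),
            ("age_band_probs", self.age_band_probs),
        ):
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for key, probs in self.risk_probs_by_gender_year.items():
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"risk probabilities for {key} must sum to 1")
        for coeffs in (self.si_coefficients, self.sa_coefficients):
            if "intercept" not in coeffs:
                raise ValueError("coefficient map must contain an 'intercept' term")
        if not 0.0 <= self.sa_no_answer_rate < 1.0:
            raise ValueError("sa_no_answer_rate must lie in [0, 1)")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(n_per_year: int = 10_000, years: tuple[str, ...] = SCHOOL_YEARS,
                   **kwargs) -> GeneratorConfig:
    cfg = GeneratorConfig(
        n_per_year=n_per_year,
        years=tuple(years),
        risk_probs_by_gender_year=default_risk_probs(tuple(years)),
        **kwargs,
    )
    cfg.validate()
    return cfg


def default_anchors(years: tuple[str, ...] = SCHOOL_YEARS) -> list[PrevalenceAnchor]:
    """Per-year prevalence anchors: the printed first/last-year values
    with linear interpolation for the unprinted intermediate years."""
    t = _year_positions(years)
    si = anchors.SI_ANCHOR_FIRST + t * (anchors.SI_ANCHOR_LAST - anchors.SI_ANCHOR_FIRST)
    sa = anchors.SA_ANCHOR_FIRST + t * (anchors.SA_ANCHOR_LAST - anchors.SA_ANCHOR_FIRST)
    return [
        PrevalenceAnchor(year, float(p_si), float(p_sa))
        for year, p_si, p_sa in zip(years, si, sa)
    ]


def _choice_index(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Inverse-CDF categorical draw; ``probs`` is (n, k) row-stochastic."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    return np.minimum((u[:, None] > cum).sum(axis=1), probs.shape[1] - 1)


def sample_covariates(
    config: GeneratorConfig, n: int, year: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw n raw records (school_year, age, gender, k10_score) for one year."""
    config.validate()
    g_probs = np.array([config.gender_probs[g] for g in GENDERS])
    gender = np.array(GENDERS)[_choice_index(rng, np.tile(g_probs, (n, 1)))]

    a_probs = np.array([config.age_band_probs[b] for b in AGE_BANDS3])
    band_idx = _choice_index(rng, np.tile(a_probs, (n, 1)))
    lo = np.array([_AGE_RANGES[b][0] for b in AGE_BANDS3])[band_idx]
    hi = np.array([_AGE_RANGES[b][1] for b in AGE_BANDS3])[band_idx]
    age = lo + np.floor(rng.random(n) * (hi - lo + 1)).astype(int)

    risk_rows = np.array(
        [config.risk_probs_by_gender_year[(g, year)] for g in GENDERS]
    )
    gender_idx = (gender == "female").astype(int)
    risk_idx = _choice_index(rng, risk_rows[gender_idx])
    k_lo = np.array([K10_BANDS[r][0] for r in RISK_LEVELS])[risk_idx]
    k_hi = np.array([K10_BANDS[r][1] for r in RISK_LEVELS])[risk_idx]
    k10 = k_lo + np.floor(rng.random(n) * (k_hi - k_lo + 1)).astype(int)

    return pd.DataFrame(
        {
            "school_year": year,
            "age": age,
            "gender": gender,
            "k10_score": k10,
        }
    )


def _coded_view(raw: pd.DataFrame) -> pd.DataFrame:
    """Minimal coded columns needed by the outcome model (no outcomes)."""
    band3 = pd.cut(
        raw["age"].clip(15, 23), bins=[14.5, 17.5, 20.5, 23.5], labels=AGE_BANDS3
    ).astype(str)
    risk = pd.cut(
        raw["k10_score"], bins=[9.5, 15.5, 29.5, 50.5], labels=RISK_LEVELS
    ).astype(str)
    era = np.where(raw["school_year"].isin(PRE_CORONA_YEARS), "pre_corona", "corona")
    return pd.DataFrame(
        {
            "school_year": raw["school_year"].to_numpy(),
            "gender": raw["gender"].to_numpy(),
            "age_band_ml": band3.map(_BAND3_TO_ML).to_numpy(),
            "risk": risk.to_numpy(),
            "era": era,
        },
        index=raw.index,
    )


def sample_outcomes(
    config: GeneratorConfig, raw: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Append raw SI/SA responses drawn from the logistic outcome models.

    SI positives get a random non-'never' response level; SA positives
    'yes'; an independent share of SA responses is replaced by
    'no_answer' (item non-response, missing completely at random).
    """
    coded = _coded_view(raw)
    out = raw.copy()
    for outcome, coeffs, offsets in (
        ("si", config.si_coefficients, config.year_offsets_si),
        ("sa", config.sa_coefficients, config.year_offsets_sa),
    ):
        p = expit(linear_predictor(coeffs, coded, offsets))
        event = rng.random(len(raw)) < p
        if outcome == "si":
            level = _SI_YES_LEVELS[
                np.floor(rng.random(len(raw)) * 3).astype(int)
            ]
            out["si"] = np.where(event, level, "never")
        else:
            sa = np.where(event, "yes", "no")
            no_ans = rng.random(len(raw)) < config.sa_no_answer_rate
            out["sa"] = np.where(no_ans, "no_answer", sa)
    return out


def _cell_table(config: GeneratorConfig, year: str) -> tuple[pd.DataFrame, np.ndarray]:
    """The 18 covariate cells (gender x age band x risk) and their
    probabilities for one year; ages within a band share one cell since
    the outcome model only sees the band."""
    rows, probs = [], []
    for gender in GENDERS:
        for band3 in AGE_BANDS3:
            for j, risk in enumerate(RISK_LEVELS):
                rows.append(
                    {
                        "school_year": year,
                        "gender": gender,
                        "age_band_ml": _BAND3_TO_ML[band3],
                        "risk": risk,
                        "era": "pre_corona" if year in PRE_CORONA_YEARS else "corona",
                    }
                )
                probs.append(
                    config.gender_probs[gender]
                    * config.age_band_probs[band3]
                    * config.risk_probs_by_gender_year[(gender, year)][j]
                )
    return pd.DataFrame(rows), np.array(probs)


def expected_prevalence(
    config: GeneratorConfig, year: str, outcome: str, offset: float = None
) -> float:
    """Analytic expected outcome prevalence for one year's covariate mixture."""
    coeffs = config.si_coefficients if outcome == "si" else config.sa_coefficients
    stored = config.year_offsets_si if outcome == "si" else config.year_offsets_sa
    if offset is None:
        offset = stored.get(year, 0.0)
    cells, probs = _cell_table(config, year)
    eta = linear_predictor(coeffs, cells) + offset
    return float(np.sum(probs * expit(eta)))


def calibrate_year_offsets(
    config: GeneratorConfig,
    anchor_list: list[PrevalenceAnchor],
    outcome: str,
    tol: float = 1e-10,
) -> dict[str, float]:
    """Solve each year's additive log-odds offset so the analytic
    expected prevalence matches the anchor (to well below 1e-8).

    The expectation is strictly increasing in the offset, so a bracketed
    1-D root find (Brent) on [-30, 30] suffices.  Offsets are stored on
    the config and returned.
    """
    config.validate()
    by_year = {a.year: a for a in anchor_list}
    missing = [y for y in config.years if y not in by_year]
    if missing:
        raise ValueError(f"anchors missing for years: {missing}")
    offsets: dict[str, float] = {}
    for year in config.years:
        target = getattr(by_year[year], outcome)
        f = lambda off: expected_prevalence(config, year, outcome, offset=off) - target
        lo, hi = -30.0, 30.0
        if f(lo) > 0 or f(hi) < 0:
            raise RuntimeError(
                f"cannot bracket calibration root for {outcome} in {year}"
            )
        offsets[year] = float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))
    stored = config.year_offsets_si if outcome == "si" else config.year_offsets_sa
    stored.clear()
    stored.update(offsets)
    return offsets


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the full multi-year raw cohort table.

    Fully reproducible from (config, seed); years are generated in the
    configured order from a single stream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    parts = []
    for year in config.years:
        raw = sample_covariates(config, config.n_per_year, year, rng)
        parts.append(sample_outcomes(config, raw, rng))
    if not parts or all(len(p) == 0 for p in parts):
        return pd.DataFrame(
            columns=["school_year", "age", "gender", "k10_score", "si", "sa"]
        )
    return pd.concat(parts, ignore_index=True)


class CohortGenerator:
    """Convenience wrapper: configure, calibrate, generate.

    Parameters
    ----------
    config : GeneratorConfig, optional
        Defaults to the study conditions (gender/age margins, rising
        risk trend, final-model outcome coefficients).
    """

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config or default_config()
        self.config.validate()
        self.calibration_: dict | None = None

    def calibrate(self, anchor_list: list[PrevalenceAnchor] | None = None):
        """Calibrate SI and SA year offsets against prevalence anchors
        (default: the printed first/last-year values, linearly
        interpolated in between).  Returns self; the per-year report is
        in ``self.calibration_``."""
        anchor_list = anchor_list or default_anchors(self.config.years)
        report = {}
        for outcome in ("si", "sa"):
            offs = calibrate_year_offsets(self.config, anchor_list, outcome)
            for year, off in offs.items():
                report.setdefault(year, {})[outcome] = {
                    "offset": off,
                    "achieved": expected_prevalence(self.config, year, outcome),
                }
        self.calibration_ = report
        return self

    def generate(self, seed: int | None = None) -> pd.DataFrame:
        return generate_cohort(self.config, seed)
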