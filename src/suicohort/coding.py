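"""Variable coding for vocational-student suicidality survey records.

Raw questionnaire responses are transformed into the analysis variables:
the Kessler K10 psychological-distress score and its low/moderate/high
risk bands, dichotomised suicidal-ideation (SI) and suicide-attempt (SA)
outcomes, clamped three-level age bands (under two labelling schemes),
and the pre-corona/corona school-year era.  Complete-case filtering with
a per-reason exclusion tally completes the module.

All coding is deterministic; no imputation is performed.  A record with
any missing K10 item gets a missing score (complete-case convention).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "SCHOOL_YEARS",
    "PRE_CORONA_YEARS",
    "CORONA_YEARS",
    "K10_BANDS",
    "AGE_BANDS3",
    "AGE_BANDS_ML",
    "SI_LEVELS",
    "SA_LEVELS",
    "GENDERS",
    "EXCLUSION_REASONS",
    "CodingError",
    "EmptyCohortError",
    "ExclusionTally",
    "canonical_school_year",
    "score_k10",
    "classify_k10",
    "dichotomize_si",
    "code_sa",
    "clamp_and_band_age",
    "classify_era",
    "code_records",
    "filter_complete",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: The ten school years covered by the study design, canonical labels.
SCHOOL_YEARS: tuple[str, ...] = tuple(f"{y}/{y + 1}" for y in range(2013, 2023))
PRE_CORONA_YEARS: tuple[str, ...] = SCHOOL_YEARS[:6]   # 2013/2014 .. 2018/2019
CORONA_YEARS: tuple[str, ...] = SCHOOL_YEARS[6:]       # 2019/2020 .. 2022/2023

#: K10 risk bands, inclusive score ranges.
K10_BANDS: dict[str, tuple[int, int]] = {
    "low": (10, 15),
    "moderate": (16, 29),
    "high": (30, 50),
}
RISK_LEVELS: tuple[str, ...] = ("low", "moderate", "high")

AGE_BANDS3: tuple[str, ...] = ("15-17", "18-20", "21-23+")
AGE_BANDS_ML: tuple[str, ...] = ("<18", "18-20", "21+")
#: The two age-band schemes share the same partition of ages.
_BAND3_TO_ML = dict(zip(AGE_BANDS3, AGE_BANDS_ML))

SI_LEVELS: tuple[str, ...] = ("never", "occasionally", "sometimes", "often")
SA_LEVELS: tuple[str, ...] = ("yes", "no", "no_answer")
GENDERS: tuple[str, ...] = ("male", "female")
ERAS: tuple[str, ...] = ("pre_corona", "corona")

#: Exclusion reasons, in the order they are applied; a record deficient in
#: several ways is counted once, under the first applicable reason.
EXCLUSION_REASONS: tuple[str, ...] = (
    "gender_other",
    "missing_gender",
    "missing_age",
    "missing_k10",
    "missing_si",
    "sa_no_answer",
    "missing_sa",
)

K10_COLUMNS: tuple[str, ...] = tuple(f"k10_{i}" for i in range(1, 11))


class CodingError(ValueError):
    """Raised when a raw value cannot be coded."""


class EmptyCohortError(RuntimeError):
    """Raised when complete-case filtering leaves no records."""


def canonical_school_year(label: str) -> str:
    """Normalize a school-year label to ``YYYY/YYYY+1``.

    Accepts both ``2013/2014`` and ``2013-2014``; any other label raises
    :class:`CodingError`.
    """
    norm = str(label).strip().replace("-", "/")
    if norm not in SCHOOL_YEARS:
        raise CodingError(f"unknown school year label: {label!r}")
    return norm


def score_k10(items) -> int:
    """Sum the ten K10 item responses (each 1..5) into a 10-50 score."""
    items = list(items)
    if len(items) != 10:
        raise CodingError(f"K10 needs exactly 10 items, got {len(items)}")
    total = 0
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise CodingError(f"K10 item {i + 1} is missing")
        v = int(v)
        if not 1 <= v <= 5:
            raise CodingError(f"K10 item {i + 1} out of range [1, 5]: {v}")
        total += v
    return total


def classify_k10(score: int) -> str:
    """Band a K10 score: low 10-15, moderate 16-29, high 30-50 (inclusive)."""
    score = int(score)
    for band, (lo, hi) in K10_BANDS.items():
        if lo <= score <= hi:
            return band
    raise CodingError(f"K10 score outside [10, 50]: {score}")


def dichotomize_si(si_raw: str | None) -> bool | None:
    """Dichotomise suicidal ideation: ``never`` -> False, any other
    response level -> True, missing -> ``None`` (record dropped later)."""
    if si_raw is None or si_raw != si_raw or si_raw == "":
        return None
    if si_raw not in SI_LEVELS:
        raise CodingError(f"unknown SI response: {si_raw!r}")
    return si_raw != "never"


def code_sa(sa_raw: str | None) -> bool | None:
    """Code suicide attempt: yes -> True, no -> False, no_answer -> None."""
    if sa_raw is None or sa_raw != sa_raw or sa_raw == "":
        return None
    if sa_raw not in SA_LEVELS:
        raise CodingError(f"unknown SA response: {sa_raw!r}")
    return {"yes": True, "no": False, "no_answer": None}[sa_raw]


def clamp_and_band_age(age_years: int) -> tuple[str, str]:
    """Clamp age to the questionnaire's 15..23+ range and band it.

    Ages below 15 are treated as 15; ages above 23 as "23 and older".
    Returns ``(band3, band_ml)`` labels, e.g. ``("15-17", "<18")``.
    """
    age = int(age_years)
    if age <= 0:
        raise CodingError(f"age must be positive, got {age}")
    age = min(max(age, 15), 23)
    if age <= 17:
        band3 = "15-17"
    elif age <= 20:
        band3 = "18-20"
    else:
        band3 = "21-23+"
    return band3, _BAND3_TO_ML[band3]


def classify_era(school_year: str) -> str:
    """Dichotomise school year: 2013/2014-2018/2019 pre_corona, later corona."""
    year = canonical_school_year(school_year)
    return "pre_corona" if year in PRE_CORONA_YEARS else "corona"


def _vector_k10_score(df: pd.DataFrame) -> pd.Series:
    """K10 score per record, NA where any item (or the score field) is missing."""
    if all(c in df.columns for c in K10_COLUMNS):
        items = df[list(K10_COLUMNS)].apply(pd.to_numeric, errors="coerce")
        bad = ((items < 1) | (items > 5)).any(axis=None)
        if bad:
            r, c = np.argwhere(((items < 1) | (items > 5)).to_numpy())[0]
            raise CodingError(
                f"K10 item {c + 1} out of range [1, 5] at row {df.index[r]}"
            )
        score = items.sum(axis=1, min_count=10)
        return score.astype("Int64")
    if "k10_score" in df.columns:
        score = pd.to_numeric(df["k10_score"], errors="coerce").astype("Int64")
        bad = score.dropna()
        if ((bad < 10) | (bad > 50)).any():
            raise CodingError("k10_score outside [10, 50]")
        return score
    raise CodingError("need k10_1..k10_10 columns or a k10_score column")


def code_records(raw: pd.DataFrame) -> pd.DataFrame:
    """Code a raw cohort table into analysis variables.

    Input columns: ``school_year``, ``age``, ``gender``, ``k10_1..k10_10``
    or ``k10_score``, ``si``, ``sa`` (missing as empty/NaN).  Output keeps
    the index and returns columns ``school_year, gender, age_band3,
    age_band_ml, era, k10_score, risk, si, sa, sa_no_answer``.  Missing
    values propagate as NA; nothing is dropped here (see
    :func:`filter_complete`).
    """
    out = pd.DataFrame(index=raw.index)
    year = raw["school_year"].astype("string").str.strip().str.replace("-", "/", regex=False)
    unknown = year.dropna()[~year.dropna().isin(SCHOOL_YEARS)]
    if len(unknown):
        raise CodingError(f"unknown school year label: {unknown.iloc[0]!r}")
    out["school_year"] = year
    out["era"] = pd.Series(
        np.where(year.isin(PRE_CORONA_YEARS), "pre_corona", "corona"),
        index=raw.index,
    ).where(year.notna())

    gender = raw["gender"].astype("string").str.strip().str.lower()
    gender = gender.replace("", pd.NA)
    known = gender.dropna()
    bad = known[~known.isin(GENDERS + ("other",))]
    if len(bad):
        raise CodingError(f"unknown gender level: {bad.iloc[0]!r}")
    out["gender"] = gender

    age = pd.to_numeric(raw["age"], errors="coerce")
    if (age.dropna() <= 0).any():
        raise CodingError("age must be positive")
    clamped = age.clip(lower=15, upper=23)
    band3 = pd.cut(
        clamped, bins=[14.5, 17.5, 20.5, 23.5], labels=AGE_BANDS3
    ).astype("string")
    out["age_band3"] = band3.where(age.notna())
    out["age_band_ml"] = out["age_band3"].map(_BAND3_TO_ML)

    score = _vector_k10_score(raw)
    out["k10_score"] = score
    risk = pd.cut(
        score.astype("float"), bins=[9.5, 15.5, 29.5, 50.5], labels=RISK_LEVELS
    ).astype("string")
    out["risk"] = risk.where(score.notna())

    si = raw["si"].astype("string").str.strip().replace("", pd.NA)
    bad = si.dropna()[~si.dropna().isin(SI_LEVELS)]
    if len(bad):
        raise CodingError(f"unknown SI response: {bad.iloc[0]!r}")
    out["si"] = (si != "never").astype("boolean").where(si.notna())

    sa = raw["sa"].astype("string").str.strip().replace("", pd.NA)
    bad = sa.dropna()[~sa.dropna().isin(SA_LEVELS)]
    if len(bad):
        raise CodingError(f"unknown SA response: {bad.iloc[0]!r}")
    out["sa_no_answer"] = (sa == "no_answer").fillna(False).astype(bool)
    out["sa"] = sa.map({"yes": True, "no": False}).astype("boolean")
    return out


@dataclass
class ExclusionTally:
    """Per-reason counts of records dropped by complete-case filtering."""

    gender_other: int = 0
    missing_gender: int = 0
    missing_age: int = 0
    missing_k10: int = 0
    missing_si: int = 0
    sa_no_answer: int = 0
    missing_sa: int = 0
    retained: int = 0
    total: int = 0

    def excluded(self) -> int:
        return sum(getattr(self, r) for r in EXCLUSION_REASONS)

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def filter_complete(
    coded: pd.DataFrame,
    required: tuple[str, ...] = ("gender", "age", "k10", "si"),
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Drop gender 'other' and records missing any required variable.

    ``required`` draws from ``{"gender", "age", "k10", "si", "sa"}``.
    Reasons are applied in :data:`EXCLUSION_REASONS` order and are
    mutually exclusive, so retained + tally sums to the input size.
    """
    valid = {"gender", "age", "k10", "si", "sa"}
    extra = set(required) - valid
    if extra:
        raise CodingError(f"unknown required variables: {sorted(extra)}")

    masks = {
        "gender_other": (coded["gender"] == "other").fillna(False).to_numpy(bool),
        "missing_gender": coded["gender"].isna().to_numpy() if "gender" in required else None,
        "missing_age": coded["age_band3"].isna().to_numpy() if "age" in required else None,
        "missing_k10": coded["k10_score"].isna().to_numpy() if "k10" in required else None,
        "missing_si": coded["si"].isna().to_numpy() if "si" in required else None,
        "sa_no_answer": coded["sa_no_answer"].to_numpy(bool) if "sa" in required else None,
        "missing_sa": (coded["sa"].isna() & ~coded["sa_no_answer"]).to_numpy()
        if "sa" in required
        else None,
    }
    remaining = np.ones(len(coded), dtype=bool)
    tally = ExclusionTally(total=len(coded))
    for reason in EXCLUSION_REASONS:
        mask = masks[reason]
        if mask is None:
            continue
        hit = mask & remaining
        setattr(tally, reason, int(hit.sum()))
        remaining &= ~hit
    kept = coded.loc[remaining].copy()
    tally.retained = len(kept)
    if tally.retained == 0:
        raise EmptyCohortError("complete-case filtering retained no records")
    return kept, tally


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a raw cohort CSV (missing values as empty fields)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.replace("", np.nan)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table with missing values as empty fields."""
    df.to_csv(path, index=False, na_rep="")
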