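"""Prevalence tables, contingency tables and trend series.

Conventions follow the study's reporting: percentages are computed on
per-variable complete cases (so per-variable Ns may differ), rendered
half-up at the printed precision (one decimal for overall and yearly
prevalence, two decimals for table cells).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .coding import CodingError

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "prevalence",
    "crosstab",
    "risk_distribution",
    "format_percent",
]


def format_percent(proportion: float, decimals: int = 1) -> str:
    """Render a proportion as a percentage, rounded half-up (matching
    the study tables, e.g. 0.154665 -> '15.47' at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(proportion) * 100)).quantize(q, ROUND_HALF_UP))


@dataclass
class ContingencyTable:
    """Level-by-outcome counts for one categorical variable.

    Levels are ordered with the reference level first; percentages are
    derived on demand, never stored.
    """

    variable: str
    outcome: str
    levels: tuple[str, ...]
    totals: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.events = np.asarray(self.events, dtype=np.int64)
        if (self.events > self.totals).any() or (self.totals < 0).any() or (
            self.events < 0
        ).any():
            raise ValueError("counts must be non-negative with events <= totals")

    @property
    def reference(self) -> str:
        return self.levels[0]

    def percentages(self) -> np.ndarray:
        return self.events / self.totals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "level": list(self.levels),
                "n": self.totals,
                "events": self.events,
                "pct": [format_percent(p, 2) for p in self.percentages()],
            }
        )


def prevalence(
    records: pd.DataFrame, outcome: str, group_by: str | None = None
) -> pd.DataFrame:
    """Outcome prevalence, overall or per group.

    Records with a missing outcome must have been filtered out by the
    caller (per-outcome complete cases).  Returns a tidy frame with
    numerator, denominator and the exact proportion; empty groups are
    omitted with a warning.
    """
    y = records[outcome]
    if y.isna().any():
        raise CodingError(f"records contain missing {outcome}; filter first")
    if group_by is None:
        groups = {"overall": records}
    else:
        observed = records[records[group_by].notna()]
        if len(observed) < len(records):
            logger.warning(
                "%d records missing %s omitted from prevalence",
                len(records) - len(observed),
                group_by,
            )
        groups = dict(tuple(observed.groupby(group_by, observed=True)))
    rows = []
    for key, grp in groups.items():
        if len(grp) == 0:
            logger.warning("empty group %r omitted", key)
            continue
        num = int(grp[outcome].astype(bool).sum())
        den = int(len(grp))
        rows.append(
            {
                "group": key,
                "numerator": num,
                "denominator": den,
                "proportion": num / den,
            }
        )
    return pd.DataFrame(rows)


def crosstab(
    records: pd.DataFrame,
    variable: str,
    outcome: str,
    levels: tuple[str, ...],
) -> ContingencyTable:
    """Per-level totals and event counts for one variable (reference
    level first in ``levels``); complete cases on (variable, outcome)."""
    sub = records[records[variable].notna() & records[outcome].notna()]
    seen = set(sub[variable].unique())
    undeclared = seen - set(levels)
    if undeclared:
        raise CodingError(
            f"undeclared level(s) {sorted(undeclared)} in {variable}"
        )
    totals, events = [], []
    for level in levels:
        grp = sub[sub[variable] == level]
        totals.append(len(grp))
        events.append(int(grp[outcome].astype(bool).sum()))
    return ContingencyTable(variable, outcome, tuple(levels), totals, events)


def risk_distribution(
    records: pd.DataFrame, group_by: str | None = None
) -> pd.DataFrame:
    """Proportion of low/moderate/high risk per group (rows sum to 1)."""
    from .coding import RISK_LEVELS

    sub = records[records["risk"].notna()]
    if group_by is None:
        sub = sub.assign(_g="overall")
        group_by = "_g"
    rows = []
    for key, grp in sub.groupby(group_by, observed=True):
        counts = grp["risk"].value_counts()
        n = len(grp)
        props = [counts.get(r, 0) / n for r in RISK_LEVELS]
        rows.append({"group": key, **dict(zip(RISK_LEVELS, props)), "n": n})
    return pd.DataFrame(rows)
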